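"""Protein similarity network construction and Markov clustering (MCL).

The family-delineation logic: all-against-all local alignment of transposase
homologs, edges kept below an E-value threshold (default 1e-4) and weighted
as -log10(E), then clustered by the Markov Cluster algorithm at a low
inflation (default 1.2), which suits the loose, interconnected structure of
IS-family similarity graphs.

The MCL implementation here is from scratch (dense numpy): alternate
expansion (matrix squaring of the column-stochastic transition matrix with
self-loops) and inflation (entrywise power followed by column
renormalization) until the matrix stops changing, then read clusters from
the attractor rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairHit:
    """One pairwise local-alignment hit (the 12-column tabular fields that
    matter downstream)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    raw_score: float
    bit_score: float
    e_value: float
    query_coverage: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


@dataclass
class HomologNetwork:
    """Undirected weighted similarity graph plus (optional) cluster labels."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    clusters: dict[str, int] | None = None
    converged: bool = True

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def n_clusters(self) -> int:
        if self.clusters is None:
            raise ValueError("network has not been clustered")
        return len(set(self.clusters.values()))


def all_vs_all_similarity(
    proteins: dict[str, str],
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    lam: float = _align.LAMBDA_GAPPED,
    k: float = _align.K_GAPPED,
) -> list[PairHit]:
    """Smith-Waterman local alignment of every unordered sequence pair
    (BLOSUM62), with Karlin-Altschul E-values ``E = K m n exp(-lambda S)``.

    Both orderings of a pair share one alignment; the hit is reported once
    per ordered pair (coverage is query-specific), and callers keep the
    better E when collapsing to undirected edges.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    hits: list[PairHit] = []
    for i, a in enumerate(ids):
        if not proteins[a]:
            warnings.warn(f"skipping empty sequence {a}")
            continue
        for b in ids[i + 1:]:
            if not proteins[b]:
                continue
            aln = _align.local_align_protein(proteins[a], proteins[b],
                                             gap_open, gap_extend)
            e = _align.karlin_altschul_evalue(
                aln["score"], len(proteins[a]), len(proteins[b]), lam, k)
            bit = (lam * aln["score"] - np.log(k)) / np.log(2)
            for q, s, qlen in ((a, b, len(proteins[a])), (b, a, len(proteins[b]))):
                hits.append(PairHit(
                    query_id=q, subject_id=s,
                    percent_identity=aln["percent_identity"],
                    alignment_length=aln["aligned_columns"],
                    raw_score=aln["score"], bit_score=bit, e_value=e,
                    query_coverage=min(1.0, aln["aligned_columns"] / qlen)))
    return hits


def read_hit_table(path) -> list[PairHit]:
    """Read a standard 12-column tab-separated local-alignment hit table
    (query, subject, %id, aln-length, mismatches, gap-opens, qstart, qend,
    sstart, send, E-value, bit-score)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qlen = abs(int(f[7]) - int(f[6])) + 1
            hits.append(PairHit(
                query_id=f[0], subject_id=f[1], percent_identity=float(f[2]),
                alignment_length=int(f[3]), raw_score=float(f[11]),
                bit_score=float(f[11]), e_value=float(f[10]),
                query_coverage=1.0 if qlen <= 0 else min(1.0, int(f[3]) / max(qlen, int(f[3])))))
    return hits


def build_network(
    hits: list[PairHit],
    e_threshold: float = 1e-4,
    e_floor: float = 1e-200,
    nodes: list[str] | None = None,
) -> HomologNetwork:
    """Keep hits with ``E < e_threshold`` as undirected edges weighted
    ``-log10(max(E, e_floor))``; self-hits are dropped and reciprocal hits
    collapse to the single best (max-weight) edge."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(sorted(nodes))
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        g.add_node(h.query_id)
        g.add_node(h.subject_id)
        if h.e_value >= e_threshold:
            continue
        w = -np.log10(max(h.e_value, e_floor))
        if g.has_edge(h.query_id, h.subject_id):
            w = max(w, g[h.query_id][h.subject_id]["weight"])
        g.add_edge(h.query_id, h.subject_id, weight=float(w))
    return HomologNetwork(graph=g)


def _mcl_matrix(network: HomologNetwork) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(network.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in network.graph.edges(data=True):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = data["weight"]
    # self-loops: max incident weight (1.0 for isolated nodes)
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    return m, nodes


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0)
    s[s == 0] = 1.0
    return m / s


def mcl_cluster(
    network: HomologNetwork,
    inflation: float = 1.2,
    pruning_threshold: float = 1e-5,
    max_iter: int = 200,
    epsilon: float = 1e-8,
) -> HomologNetwork:
    """Cluster the network in place with the Markov Cluster algorithm.

    Alternates expansion (``M @ M``) and inflation (entrywise power
    ``inflation`` with column renormalization, then pruning of entries below
    ``pruning_threshold``) until the matrix change falls below ``epsilon`` or
    ``max_iter`` is reached (non-convergence keeps the current partition and
    clears the ``converged`` flag).  Clusters are read from attractor rows;
    a node attracted to several clusters goes to the one whose smallest
    attractor label sorts first.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    m, nodes = _mcl_matrix(network)
    m = _normalize_columns(m)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < pruning_threshold] = 0.0
        m = _normalize_columns(m)
        if np.abs(m - prev).max() < epsilon:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    clusters = _read_attractor_clusters(m, nodes)
    network.clusters = clusters
    network.converged = converged
    nx.set_node_attributes(network.graph, clusters, "cluster")
    return network


def _read_attractor_clusters(m: np.ndarray, nodes: list[str],
                             tol: float = 1e-6) -> dict[str, int]:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > tol]
    if not attractors:  # degenerate fallback: every node its own cluster
        return {nodes[i]: i for i in range(n)}
    # merge attractors that share any attracted node (overlapping rows)
    parent = list(range(len(attractors)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = [set(np.nonzero(m[i] > tol)[0]) | {i} for i in attractors]
    for i in range(len(attractors)):
        for j in range(i + 1, len(attractors)):
            if rows[i] & rows[j]:
                parent[find(j)] = find(i)

    group_of = {}
    for ai, a in enumerate(attractors):
        group_of[a] = find(ai)
    # deterministic labels: order groups by smallest attractor node label
    groups: dict[int, list[int]] = {}
    for a in attractors:
        groups.setdefault(group_of[a], []).append(a)
    ordered = sorted(groups.values(), key=lambda ats: min(nodes[a] for a in ats))
    label_of_attractor = {a: lbl for lbl, ats in enumerate(ordered) for a in ats}

    clusters: dict[str, int] = {}
    next_label = len(ordered)
    for j in range(n):
        pulls = [a for a in attractors if m[a, j] > tol]
        if pulls:
            clusters[nodes[j]] = min(label_of_attractor[a] for a in pulls)
        else:
            clusters[nodes[j]] = next_label
            next_label += 1
    return clusters


def export_network(network: HomologNetwork, prefix) -> dict[str, str]:
    """Write edge-list TSV, GraphML, and (when clustered) a cluster TSV.

    Returns the paths written, keyed by kind.
    """
    prefix = str(prefix)
    paths = {}
    edge_path = prefix + ".edges.tsv"
    with open(edge_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.6f}\n")
    paths["edges"] = edge_path
    graphml_path = prefix + ".graphml"
    nx.write_graphml(network.graph, graphml_path)
    paths["graphml"] = graphml_path
    if network.clusters is not None:
        cl_path = prefix + ".clusters.tsv"
        with open(cl_path, "w") as fh:
            fh.write("node\tcluster\n")
            for node in sorted(network.clusters):
                fh.write(f"{node}\t{network.clusters[node]}\n")
        paths["clusters"] = cl_path
    return paths


def read_edge_tsv(path) -> HomologNetwork:
    """Round-trip reader for the edge-list TSV written by export_network."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node_a"):
            raise ValueError("not an edge-list TSV")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            g.add_edge(a, b, weight=float(w))
    return HomologNetwork(graph=g)
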