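"""Iterative profile-based homolog expansion over a FASTA protein database.

The search protocol: a seed transposase queries the database with a
substitution matrix, hits are filtered on E-value (<= 0.005) and query
coverage (>= 60%), a position-specific scoring profile is built from the
retained hits and searched once more, and then the *most distantly related*
retained hit (by an average-distance/UPGMA tree on BLOSUM62-derived
distances) becomes the next round's query.  Propagating through distant
homologs in this way overcomes the query dependence of a single-query
search and recovers families undetectable from the seed directly.

Profile construction uses Henikoff position-based sequence weighting and
pseudocount blending against background residue frequencies -- a simplified
stand-in for a full PSI-Blast profile (no compositional adjustment).
Profile-score statistics are calibrated per search by fitting a Gumbel
distribution to scores of shuffled decoy sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from . import _align
from ._align import AA, AA_INDEX

logger = logging.getLogger(__name__)

#: background amino-acid frequencies (Robinson & Robinson), ordered as AA
BACKGROUND = np.array([
    0.0780, 0.0192, 0.0536, 0.0629, 0.0397, 0.0738, 0.0219, 0.0514,
    0.0574, 0.0901, 0.0224, 0.0448, 0.0520, 0.0426, 0.0512, 0.0712,
    0.0584, 0.0644, 0.0132, 0.0321,
])
BACKGROUND /= BACKGROUND.sum()

_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class CascadeHit:
    """One retained hit with the round and scoring route that admitted it."""

    hit_id: str
    round_index: int
    e_value: float
    coverage: float
    via: str  # "matrix" | "profile"


@dataclass
class ProfileModel:
    """Position-specific log-odds profile built from an implicit query-anchored
    alignment of retained hits."""

    scores: np.ndarray  # (L, 20) log-odds, natural log units
    query_id: str
    source_ids: tuple[str, ...]
    pseudocount_weight: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class CascadeResult:
    """Cumulative, deduplicated hit set with provenance."""

    hits: dict[str, CascadeHit] = field(default_factory=dict)
    queries: list[str] = field(default_factory=list)
    exhausted: bool = False
    rounds_run: int = 0

    def hits_through_round(self, r: int) -> set[str]:
        return {h.hit_id for h in self.hits.values() if h.round_index <= r}


def matrix_search(
    query_id: str,
    query_seq: str,
    database: dict[str, str],
    e_max: float = 0.005,
    cov_min: float = 0.6,
) -> dict[str, tuple[float, float]]:
    """Substitution-matrix (BLOSUM62 Smith-Waterman) search of the database.

    Returns ``{hit_id: (e_value, coverage)}`` for hits passing both filters.
    Coverage is the fraction of the query spanned by the alignment.
    """
    if not database:
        raise ValueError("empty database")
    out: dict[str, tuple[float, float]] = {}
    for sid, sseq in database.items():
        if not sseq:
            logger.warning("skipping empty sequence %s", sid)
            continue
        aln = _align.local_align_protein(query_seq, sseq)
        e = _align.karlin_altschul_evalue(aln["score"], len(query_seq), len(sseq))
        cov = aln["coverage"]
        if e <= e_max and cov >= cov_min:
            out[sid] = (e, cov)
    return out


def build_profile(
    query_id: str,
    query_seq: str,
    hit_seqs: dict[str, str],
    pseudocount_weight: float = 5.0,
) -> ProfileModel:
    """Build a query-length log-odds profile from retained hits.

    Each hit is locally aligned to the query and its residues stacked onto
    query columns.  Sequences get Henikoff position-based weights; observed
    frequencies are blended with background frequencies using
    ``pseudocount_weight`` pseudocounts per column.
    """
    L = len(query_seq)
    ids = [query_id] + sorted(set(hit_seqs) - {query_id})
    # residue index per column per sequence (-1 = unaligned)
    rows = np.full((len(ids), L), -1, dtype=np.int64)
    rows[0] = _align.encode_protein(query_seq)
    for r, sid in enumerate(ids[1:], start=1):
        mapping = _align.pairwise_query_mapping(query_seq, hit_seqs[sid])
        enc = _align.encode_protein(hit_seqs[sid])
        mask = mapping >= 0
        rows[r, mask] = enc[mapping[mask]]

    # Henikoff position-based weights
    raw = np.zeros(len(ids))
    for j in range(L):
        col = rows[:, j]
        present = col >= 0
        if present.sum() == 0:
            continue
        vals, counts = np.unique(col[present], return_counts=True)
        r_distinct = len(vals)
        count_of = dict(zip(vals.tolist(), counts.tolist()))
        for i in np.nonzero(present)[0]:
            raw[i] += 1.0 / (r_distinct * count_of[int(col[i])])
    if raw.sum() == 0:
        raw[:] = 1.0
    weights = raw / raw.sum()

    scores = np.zeros((L, 20))
    for j in range(L):
        col = rows[:, j]
        present = col >= 0
        freq = np.zeros(20)
        for i in np.nonzero(present)[0]:
            freq[col[i]] += weights[i]
        total = freq.sum()
        if total > 0:
            freq /= total
        n_eff = max(1.0, present.sum())
        p = (n_eff * freq + pseudocount_weight * BACKGROUND) / (n_eff + pseudocount_weight)
        scores[j] = np.log(p / BACKGROUND)
    return ProfileModel(scores=scores, query_id=query_id,
                        source_ids=tuple(ids), pseudocount_weight=pseudocount_weight)


def calibrate_profile(
    profile: ProfileModel,
    database: dict[str, str],
    rng: np.random.Generator,
    n_decoys: int = 40,
) -> tuple[float, float]:
    """Fit Gumbel location/scale to profile scores of shuffled decoys.

    Decoys are residue shuffles of database sequences (composition
    preserved).  Returns (lambda, mu) by the method of moments.
    """
    seqs = sorted(database.values(), key=len, reverse=True)
    scores = []
    i = 0
    while len(scores) < n_decoys:
        s = seqs[i % len(seqs)]
        arr = _align.encode_protein(s)
        rng.shuffle(arr)
        sc, _, _ = _align.sw_profile(profile.scores, arr)
        scores.append(sc)
        i += 1
    scores = np.asarray(scores)
    std = scores.std(ddof=1)
    if std < 1e-9:
        std = 1e-9
    lam = math.pi / (std * math.sqrt(6.0))
    mu = scores.mean() - _EULER_GAMMA / lam
    return lam, mu


def profile_search(
    profile: ProfileModel,
    database: dict[str, str],
    e_max: float = 0.005,
    cov_min: float = 0.6,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[float, float]]:
    """Search the database with a position-specific profile.

    E-values come from a per-search Gumbel calibration on shuffled decoys:
    ``E = N * P(S >= s)`` with N the database size.  Coverage is the aligned
    fraction of the profile.
    """
    if not database:
        raise ValueError("empty database")
    if rng is None:
        rng = np.random.default_rng(0)
    lam, mu = calibrate_profile(profile, database, rng)
    n_db = len(database)
    out: dict[str, tuple[float, float]] = {}
    for sid, sseq in database.items():
        if not sseq:
            continue
        enc = _align.encode_protein(sseq)
        score, (p0, p1), _ = _align.sw_profile(profile.scores, enc)
        # Gumbel upper tail
        z = lam * (score - mu)
        pval = 1.0 - math.exp(-math.exp(-z)) if z < 30 else math.exp(-z)
        e = n_db * pval
        cov = (p1 - p0) / profile.length
        if e <= e_max and cov >= cov_min:
            out[sid] = (e, cov)
    return out


def blosum62_distance_matrix(seqs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances 1 - S(a,b)/min(S(a,a), S(b,b)) from BLOSUM62 local
    alignment scores (the average-distance-tree input)."""
    ids = sorted(seqs)
    n = len(ids)
    self_score = {i: _align.local_align_protein(seqs[i], seqs[i])["score"] for i in ids}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = _align.local_align_protein(seqs[ids[i]], seqs[ids[j]])["score"]
            denom = min(self_score[ids[i]], self_score[ids[j]])
            dist = 1.0 - s / denom if denom > 0 else 1.0
            d[i, j] = d[j, i] = max(0.0, dist)
    return d, ids


def select_next_query(
    hit_seqs: dict[str, str],
    current_query: str,
    used_queries: set[str],
) -> str:
    """Choose the unused retained hit most distant from the current query on
    an average-distance (UPGMA) tree built from BLOSUM62 pairwise distances.

    Ties break to the lexicographically smallest label.  Raises
    ``CascadeExhausted`` when every hit has already served as a query.
    """
    candidates = sorted(set(hit_seqs) - set(used_queries) - {current_query})
    if not candidates:
        raise CascadeExhausted("all retained hits have been used as queries")
    if len(candidates) == 1:
        return candidates[0]
    pool = {current_query: hit_seqs[current_query], **{c: hit_seqs[c] for c in candidates}}
    d, ids = blosum62_distance_matrix(pool)
    if len(ids) == 2:
        return candidates[0]
    z = linkage(squareform(d, checks=False), method="average")
    coph = squareform(cophenet(z))
    qi = ids.index(current_query)
    best, best_d = None, -1.0
    for c in candidates:
        cd = coph[qi, ids.index(c)]
        if cd > best_d + 1e-12 or (abs(cd - best_d) <= 1e-12 and (best is None or c < best)):
            best, best_d = c, cd
    return best


class CascadeExhausted(Exception):
    """No unused retained hit remains to continue the cascade."""


def run_cascade(
    seed_query: str | tuple[str, str],
    database: dict[str, str],
    max_rounds: int = 7,
    e_max: float = 0.005,
    cov_min: float = 0.6,
    seed: int = 0,
) -> CascadeResult:
    """Run the full cascade: per round, a matrix search then one profile
    search from the current query, both filtered on E-value and coverage;
    the next query is the most tree-distant unused retained hit.

    ``seed_query`` is a database id or an ``(id, sequence)`` pair.  Stops at
    ``max_rounds`` or when the hit set is exhausted.  The result's hit set is
    cumulative and monotone nondecreasing across rounds.
    """
    rng = np.random.default_rng(seed)
    result = CascadeResult()
    if max_rounds <= 0:
        return result
    if isinstance(seed_query, tuple):
        qid, qseq = seed_query
    else:
        qid, qseq = seed_query, database[seed_query]

    used: set[str] = set()
    for round_index in range(1, max_rounds + 1):
        used.add(qid)
        result.queries.append(qid)
        result.rounds_run = round_index

        mhits = matrix_search(qid, qseq, database, e_max, cov_min)
        for sid, (e, cov) in mhits.items():
            if sid not in result.hits:
                result.hits[sid] = CascadeHit(sid, round_index, e, cov, "matrix")

        profile = build_profile(qid, qseq,
                                {s: database[s] for s in mhits if s in database})
        phits = profile_search(profile, database, e_max, cov_min, rng=rng)
        for sid, (e, cov) in phits.items():
            if sid not in result.hits:
                result.hits[sid] = CascadeHit(sid, round_index, e, cov, "profile")

        logger.info("round %d query=%s matrix=%d profile=%d cumulative=%d",
                    round_index, qid, len(mhits), len(phits), len(result.hits))
        if round_index == max_rounds:
            break
        try:
            pool = {s: database[s] for s in result.hits if s in database}
            pool.setdefault(qid, qseq)
            nxt = select_next_query(pool, qid, used)
        except CascadeExhausted:
            result.exhausted = True
            break
        qid, qseq = nxt, database[nxt]
    return result
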