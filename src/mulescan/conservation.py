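"""Alignment-based conservation profiling and motif discovery.

Operations on protein multiple alignments of transposase families:

* gap-majority column filtering (columns with >60% gaps dropped);
* windowed conservation curves -- the per-column mean of all pairwise
  BLOSUM62 scores, averaged over a centered window (15 aa for domain-level
  plots, 10 aa for differential comparisons), the plotcon-style statistic;
* anchoring of the catalytic DDE triad from a reference sequence through
  the alignment onto every row, plus the C/D(2)H signature scan 11-19 aa
  downstream of D2;
* localization of the top conserved regions (the N1/N2 N-terminal anchor
  domains and the catalytic core);
* differential conservation between two alignments sharing a reference
  group, which isolates regions conserved only with one partner group
  (e.g. the promoter-targeting signature between N1 and N2).

Gap handling in pair scores: a gap against a residue scores -4; gap-gap
pairs are excluded from the average.  Windows shrink at alignment edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import AA_INDEX, blosum62_20x20

logger = logging.getLogger(__name__)

GAP = "-"
GAP_SCORE = -4.0


@dataclass
class AlignmentBlock:
    """An alignment: equal-length rows plus a column -> residue-index map."""

    ids: list[str]
    rows: list[str]
    column_map: np.ndarray = field(default=None, repr=False)  # (n_rows, n_cols)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.column_map is None:
            self.column_map = _build_column_map(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_fasta(cls, path) -> "AlignmentBlock":
        from Bio import AlignIO
        aln = AlignIO.read(str(path), "fasta")
        return cls(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln])

    @classmethod
    def from_stockholm(cls, path) -> "AlignmentBlock":
        from Bio import AlignIO
        aln = AlignIO.read(str(path), "stockholm")
        return cls(ids=[r.id for r in aln],
                   rows=[str(r.seq).upper().replace(".", GAP) for r in aln])


def _build_column_map(rows: list[str]) -> np.ndarray:
    n, L = len(rows), len(rows[0]) if rows else 0
    cmap = np.full((n, L), -1, dtype=np.int64)
    for i, row in enumerate(rows):
        k = 0
        for j, c in enumerate(row):
            if c != GAP:
                cmap[i, j] = k
                k += 1
    return cmap


def filter_gap_columns(alignment: AlignmentBlock,
                       max_gap_frac: float = 0.6) -> AlignmentBlock:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_frac``."""
    if alignment.n_columns == 0:
        raise ValueError("empty alignment")
    n = len(alignment.rows)
    keep = [j for j in range(alignment.n_columns)
            if sum(r[j] == GAP for r in alignment.rows) / n <= max_gap_frac]
    if not keep:
        raise ValueError("all columns removed by gap filter")
    rows = ["".join(r[j] for j in keep) for r in alignment.rows]
    return AlignmentBlock(ids=list(alignment.ids), rows=rows)


# ---------------------------------------------------------------------------
# Windowed conservation
# ---------------------------------------------------------------------------

def _encode_rows(rows: list[str]) -> np.ndarray:
    """Residue indices, -1 for gaps/unknowns."""
    n, L = len(rows), len(rows[0])
    enc = np.full((n, L), -1, dtype=np.int64)
    for i, row in enumerate(rows):
        for j, c in enumerate(row):
            enc[i, j] = AA_INDEX.get(c, -1) if c != GAP else -1
    return enc


def column_scores(rows: list[str], gap_score: float = GAP_SCORE) -> np.ndarray:
    """Mean pairwise BLOSUM62 score per column (gap-vs-residue scored
    ``gap_score``, gap-vs-gap pairs excluded)."""
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    enc = _encode_rows(rows)
    mat = blosum62_20x20()
    n, L = enc.shape
    out = np.zeros(L)
    for j in range(L):
        col = enc[:, j]
        total = 0.0
        pairs = 0
        for a in range(n):
            for b in range(a + 1, n):
                x, y = col[a], col[b]
                if x < 0 and y < 0:
                    continue
                total += gap_score if (x < 0 or y < 0) else mat[x, y]
                pairs += 1
        out[j] = total / pairs if pairs else 0.0
    return out


def windowed_conservation(
    alignment: AlignmentBlock | list[str],
    window: int = 15,
    gap_score: float = GAP_SCORE,
) -> np.ndarray:
    """Sliding-window conservation profile: the mean of column scores over a
    centered window of ``window`` columns, shrunk at the edges.  With
    ``window=1`` this equals the raw column scores."""
    rows = alignment.rows if isinstance(alignment, AlignmentBlock) else list(alignment)
    cs = column_scores(rows, gap_score=gap_score)
    L = len(cs)
    half = window // 2
    out = np.empty(L)
    for j in range(L):
        lo = max(0, j - half)
        hi = min(L, j + window - half)
        out[j] = cs[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# Triad anchoring and the C/D(2)H signature
# ---------------------------------------------------------------------------

@dataclass
class TriadCall:
    """Per-row DDE triad (residue indices in the ungapped sequence)."""

    seq_id: str
    d1: int | None
    d2: int | None
    e: int | None
    cdh_offset: int | None = None
    insert_length: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return None not in (self.d1, self.d2, self.e)


def anchor_triad(
    alignment: AlignmentBlock,
    reference_id: str,
    reference_triad: tuple[int, int, int],
    cdh_range: tuple[int, int] = (11, 19),
) -> list[TriadCall]:
    """Map the reference catalytic triad through alignment columns onto
    every row.

    A position is flagged when the row holds a gap there or a residue
    outside {D, E}; rows with a called D2 are also scanned for the C/D(2)H
    signature downstream.  ``insert_length`` is the per-row D2 -> E distance
    in residues.
    """
    if reference_id not in alignment.ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref_i = alignment.ids.index(reference_id)
    ref_map = alignment.column_map[ref_i]
    cols = []
    for pos in reference_triad:
        hits = np.nonzero(ref_map == pos)[0]
        if len(hits) != 1:
            raise ValueError(f"reference triad index {pos} invalid")
        cols.append(int(hits[0]))
    d1c, d2c, ec = cols
    if not d1c < d2c < ec:
        raise ValueError("reference triad must be strictly increasing")

    calls: list[TriadCall] = []
    for i, seq_id in enumerate(alignment.ids):
        row = alignment.rows[i]
        ungapped = row.replace(GAP, "")
        call = TriadCall(seq_id=seq_id, d1=None, d2=None, e=None)
        vals = []
        for col, want, name in ((d1c, "D", "d1"), (d2c, "D", "d2"), (ec, "E", "e")):
            c = row[col]
            if c == GAP:
                call.flags.append(f"{name}_gapped")
                vals.append(None)
                continue
            idx = int(alignment.column_map[i, col])
            if c not in ("D", "E"):
                call.flags.append(f"{name}_non_acidic:{c}")
            vals.append(idx)
        call.d1, call.d2, call.e = vals
        if call.d2 is not None and call.e is not None:
            call.insert_length = call.e - call.d2
        if call.d2 is not None:
            call.cdh_offset = scan_cdh_motif(ungapped, call.d2, cdh_range)
        calls.append(call)
    return calls


def scan_cdh_motif(sequence: str, d2_index: int,
                   offset_range: tuple[int, int] = (11, 19)) -> int | None:
    """Offset (aa downstream of D2) of the nearest ``[CD] x x H`` signature
    within ``offset_range``, or None."""
    lo, hi = offset_range
    for off in range(lo, hi + 1):
        p = d2_index + off
        if p + 3 >= len(sequence):
            break
        if sequence[p] in "CD" and sequence[p + 3] == "H":
            return off
    return None


# ---------------------------------------------------------------------------
# Conserved-domain localization and differential conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservedRegion:
    start: int  # column (or reference-residue) coordinates, half-open
    end: int
    mean_score: float


def locate_anchor_domains(
    profile: np.ndarray,
    n_domains: int = 3,
    threshold: float | None = None,
    min_width: int = 5,
) -> list[ConservedRegion]:
    """The ``n_domains`` best non-overlapping conserved regions of a profile.

    Candidate regions are maximal runs above ``threshold`` (default: profile
    mean + 0.5 sd) at least ``min_width`` columns wide; they are taken
    greedily best-mean-first and returned ordered by position.  Fewer
    regions than requested are returned as-is.
    """
    profile = np.asarray(profile, dtype=float)
    if threshold is None:
        threshold = float(profile.mean() + 0.5 * profile.std())
    above = profile > threshold
    runs = []
    j = 0
    while j < len(profile):
        if above[j]:
            k = j
            while k < len(profile) and above[k]:
                k += 1
            if k - j >= min_width:
                runs.append(ConservedRegion(j, k, float(profile[j:k].mean())))
            j = k
        else:
            j += 1
    chosen: list[ConservedRegion] = []
    for r in sorted(runs, key=lambda r: (-r.mean_score, r.start)):
        if len(chosen) == n_domains:
            break
        if all(r.end <= c.start or r.start >= c.end for c in chosen):
            chosen.append(r)
    if len(chosen) < n_domains:
        logger.info("only %d of %d requested conserved regions found",
                    len(chosen), n_domains)
    return sorted(chosen, key=lambda r: r.start)


@dataclass
class SignatureRegion:
    """A differentially conserved segment, in reference-residue coordinates,
    with its consensus PFM over the first alignment's rows."""

    start: int
    end: int
    mean_delta: float
    pfm: pd.DataFrame
    consensus: str


def _project_to_reference(alignment: AlignmentBlock, profile: np.ndarray,
                          reference_id: str) -> np.ndarray:
    """Profile values at the reference row's ungapped positions."""
    i = alignment.ids.index(reference_id)
    cmap = alignment.column_map[i]
    cols = np.nonzero(cmap >= 0)[0]
    out = np.full(int(cmap.max()) + 1, np.nan)
    out[cmap[cols]] = profile[cols]
    return out


def differential_conservation(
    alignment_ab1: AlignmentBlock,
    alignment_ab2: AlignmentBlock,
    window: int = 10,
    delta_min: float = 1.0,
    run_min: int = 8,
    reference_id: str | None = None,
) -> list[SignatureRegion]:
    """Regions more conserved with partner group B1 than with B2.

    Both alignments must share the reference-group rows; windowed profiles
    are computed for each, projected onto the ungapped coordinates of a
    shared reference row, and maximal runs where
    ``profile(A+B1) - profile(A+B2) > delta_min`` for at least ``run_min``
    residues are reported with the consensus (PFM) of the first alignment
    over each region.
    """
    shared = sorted(set(alignment_ab1.ids) & set(alignment_ab2.ids))
    if not shared:
        raise ValueError("alignments share no rows")
    ref = reference_id if reference_id is not None else shared[0]
    if ref not in shared:
        raise ValueError("reference row must be present in both alignments")

    p1 = _project_to_reference(alignment_ab1,
                               windowed_conservation(alignment_ab1, window), ref)
    p2 = _project_to_reference(alignment_ab2,
                               windowed_conservation(alignment_ab2, window), ref)
    L = min(len(p1), len(p2))
    delta = p1[:L] - p2[:L]
    ok = np.isfinite(delta) & (delta > delta_min)

    regions: list[SignatureRegion] = []
    j = 0
    while j < L:
        if ok[j]:
            k = j
            while k < L and ok[k]:
                k += 1
            if k - j >= run_min:
                regions.append(_signature_region(alignment_ab1, ref, j, k,
                                                 float(np.nanmean(delta[j:k]))))
            j = k
        else:
            j += 1
    return regions


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _signature_region(alignment: AlignmentBlock, reference_id: str,
                      start: int, end: int, mean_delta: float) -> SignatureRegion:
    i = alignment.ids.index(reference_id)
    cmap = alignment.column_map[i]
    cols = [int(np.nonzero(cmap == p)[0][0]) for p in range(start, end)
            if (cmap == p).any()]
    counts = np.zeros((len(cols), 20))
    for r, row in enumerate(alignment.rows):
        for ci, col in enumerate(cols):
            c = row[col]
            if c in AA_INDEX:
                counts[ci, AA_INDEX[c]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    freqs = counts / sums
    consensus = "".join(_AA20[int(np.argmax(f))] if f.max() > 0 else "X"
                        for f in freqs)
    pfm = pd.DataFrame(freqs, columns=list(_AA20))
    pfm.index = pd.RangeIndex(start, end, name="reference_position")
    return SignatureRegion(start=start, end=end, mean_delta=mean_delta,
                           pfm=pfm, consensus=consensus)


def write_profile_tsv(profile: np.ndarray, path) -> None:
    pd.DataFrame({"column": np.arange(len(profile)),
                  "score": profile}).to_csv(path, sep="\t", index=False)
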