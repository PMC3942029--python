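"""Shared alignment primitives: BLOSUM62 access, local alignment summaries,
Karlin–Altschul statistics, and a profile-vs-sequence Smith–Waterman kernel.

These are the low-level pieces used by the similarity-network, cascade-search
and conservation modules.  Pairwise sequence alignment is delegated to
Biopython's C PairwiseAligner; only the position-specific-profile alignment,
which no installed library provides, is implemented here (numba-compiled).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

#: canonical amino-acid alphabet used throughout (index order matters for
#: profile matrices and conservation scoring)
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: canonical nucleotide alphabet
NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}

# Gapped BLOSUM62 Karlin-Altschul constants (open 11 / extend 1),
# the standard published defaults; configurable at call sites.
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041


@lru_cache(maxsize=1)
def blosum62():
    """The BLOSUM62 substitution matrix (Biopython Array)."""
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=1)
def blosum62_20x20() -> np.ndarray:
    """BLOSUM62 restricted to the 20 standard residues, ordered as :data:`AA`."""
    m = blosum62()
    out = np.zeros((20, 20), dtype=np.float64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = m[a, b]
    return out


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string as indices into :data:`AA` (unknowns -> 0)."""
    return np.asarray([AA_INDEX.get(c, 0) for c in seq.upper()], dtype=np.int64)


@lru_cache(maxsize=4)
def _protein_aligner(open_gap: float, extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def local_align_protein(a: str, b: str, gap_open: float = -11.0,
                        gap_extend: float = -1.0):
    """Smith–Waterman local alignment of two protein sequences.

    Returns a dict with ``score``, ``identities``, ``aligned_columns``,
    ``percent_identity``, ``q_span`` (aligned span on *a*) and ``coverage``
    (q_span / len(a)).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _protein_aligner(gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    qa = aln.aligned[0]
    q_span = int(qa[-1][1] - qa[0][0]) if len(qa) else 0
    return {
        "score": float(aln.score),
        "identities": int(counts.identities),
        "aligned_columns": int(columns),
        "percent_identity": 100.0 * counts.identities / columns if columns else 0.0,
        "q_span": q_span,
        "coverage": q_span / len(a),
    }


def pairwise_query_mapping(query: str, hit: str, gap_open: float = -11.0,
                           gap_extend: float = -1.0) -> np.ndarray:
    """Map hit residues onto query positions via local alignment.

    Returns an int array of length ``len(query)`` holding, for each query
    position, the index of the aligned residue in *hit* or -1.
    """
    aligner = _protein_aligner(gap_open, gap_extend)
    aln = aligner.align(query.upper(), hit.upper())[0]
    mapping = np.full(len(query), -1, dtype=np.int64)
    qa, ha = aln.aligned
    for (qs, qe), (hs, he) in zip(qa, ha):
        mapping[qs:qe] = np.arange(hs, he)
    return mapping


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = LAMBDA_GAPPED,
                           k: float = K_GAPPED) -> float:
    """Expected number of chance alignments: E = K * m * n * exp(-lambda * S)."""
    return k * m * n * math.exp(-lam * score)


def percent_identity_full(a: str, b: str) -> float:
    """Ungapped identity of two equal-length strings (percent)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


# ---------------------------------------------------------------------------
# Profile-vs-sequence Smith-Waterman (affine gaps), numba-compiled.
# ---------------------------------------------------------------------------

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _sw_profile_kernel(profile, seq, gap_open, gap_extend):
    """Affine-gap local alignment of a position-specific score profile
    (L x 20) against an encoded sequence.  Returns
    (best_score, profile_start, profile_end, seq_start, seq_end)."""
    L = profile.shape[0]
    n = seq.shape[0]
    H = np.zeros(n + 1, dtype=np.float64)
    E = np.zeros(n + 1, dtype=np.float64)
    # origin bookkeeping: for each cell remember where its local path started
    start_i = np.zeros(n + 1, dtype=np.int64)
    start_j = np.zeros(n + 1, dtype=np.int64)
    e_start_i = np.zeros(n + 1, dtype=np.int64)
    e_start_j = np.zeros(n + 1, dtype=np.int64)
    best = 0.0
    bi = 0
    bj = 0
    bsi = 0
    bsj = 0
    for i in range(1, L + 1):
        diag = 0.0
        diag_si = i - 1
        diag_sj = 0
        F = 0.0
        f_si = 0
        f_sj = 0
        for j in range(1, n + 1):
            # E: gap in profile (consume seq)
            e_open = H[j - 1] + gap_open
            e_ext = E[j - 1] + gap_extend
            if e_open >= e_ext:
                E[j] = e_open
                e_start_i[j] = start_i[j - 1]
                e_start_j[j] = start_j[j - 1]
            else:
                E[j] = e_ext
                e_start_i[j] = e_start_i[j - 1]
                e_start_j[j] = e_start_j[j - 1]
            # F: gap in sequence (consume profile)
            f_open = H[j] + gap_open
            f_ext = F + gap_extend
            if f_open >= f_ext:
                F = f_open
                f_si = start_i[j]
                f_sj = start_j[j]
            else:
                F = f_ext
            m = diag + profile[i - 1, seq[j - 1]]
            m_si = diag_si
            m_sj = diag_sj
            if diag <= 0.0:
                m = profile[i - 1, seq[j - 1]]
                m_si = i - 1
                m_sj = j - 1
            # save H[j] (row i-1) as next diagonal before overwriting
            diag = H[j]
            diag_si = start_i[j]
            diag_sj = start_j[j]
            h = m
            h_si = m_si
            h_sj = m_sj
            if E[j] > h:
                h = E[j]
                h_si = e_start_i[j]
                h_sj = e_start_j[j]
            if F > h:
                h = F
                h_si = f_si
                h_sj = f_sj
            if h < 0.0:
                h = 0.0
                h_si = i
                h_sj = j
            H[j] = h
            start_i[j] = h_si
            start_j[j] = h_sj
            if h > best:
                best = h
                bi = i
                bj = j
                bsi = h_si
                bsj = h_sj
    return best, bsi, bi, bsj, bj


def sw_profile(profile: np.ndarray, seq_encoded: np.ndarray,
               gap_open: float = -11.0, gap_extend: float = -1.0):
    """Local alignment of an (L, 20) log-odds profile against an encoded
    protein.  Returns (score, (p_start, p_end), (s_start, s_end))."""
    score, pi0, pi1, sj0, sj1 = _sw_profile_kernel(
        np.ascontiguousarray(profile, dtype=np.float64),
        np.ascontiguousarray(seq_encoded, dtype=np.int64),
        float(gap_open), float(gap_extend))
    return float(score), (int(pi0), int(pi1)), (int(sj0), int(sj1))
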