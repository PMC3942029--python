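"""Insertion-site specificity analysis.

Quantifies where elements insert relative to sigma-A (housekeeping)
promoters: 300 bp junction flanks are extracted on both sides of each
validated element (identical insertions deduplicated first), scanned with a
paired -35/-10 position-weight-matrix model (spacer 15-19 bp), and the hits
are summarized as a positional enrichment profile -- for each distance d
within +/-30 bp of the junction, the fraction of all detected promoters
whose -35 box starts at that distance.  IRl-side junctions get negative
distances, IRr-side positive, so an element family that targets promoters at
a fixed distance from its right IR shows a single positive-side peak.

Also provided: the orientation-bias statistic (fraction of elements whose
IRr faces the nearest detected promoter) and the IUPAC consensus of the
duplicated target sites (DRs).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import revcomp

logger = logging.getLogger(__name__)

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}

#: IUPAC code for each non-empty subset of bases
_IUPAC_OF = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class JunctionFlank:
    """One 300 bp genomic flank reading away from an element."""

    te_id: str
    side: str  # "IRl" | "IRr"
    sequence: str
    truncated: bool = False

    @property
    def dedup_key(self) -> str:
        h = hashlib.sha1(f"{self.side}:{self.sequence}".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class PromoterHit:
    """A paired -35/-10 match; ``pos_minus35`` is the 0-based offset of the
    -35 box start from the junction (flank start)."""

    pos_minus35: int
    spacer: int
    score: float
    strand: str = "+"

    def __post_init__(self):
        if not 15 <= self.spacer <= 19:
            raise ValueError("spacer must lie in [15, 19]")


@dataclass
class JunctionProfile:
    """Per-position promoter-detection ratios around IR/genome junctions."""

    ratios: dict[int, float]
    n_promoters_total: int
    n_junctions: int
    horizon: int

    @property
    def defined(self) -> bool:
        return self.n_promoters_total > 0

    @property
    def peak_position(self) -> int | None:
        if not self.defined:
            return None
        return max(sorted(self.ratios), key=lambda d: self.ratios[d])

    @property
    def peak_ratio(self) -> float | None:
        if not self.defined:
            return None
        return self.ratios[self.peak_position]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": sorted(self.ratios),
                             "ratio": [self.ratios[d] for d in sorted(self.ratios)]})


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

def extract_junction_flanks(
    annotations,
    genome: str,
    flank: int = 300,
    dedup: bool = True,
) -> list[JunctionFlank]:
    """Two flanks per element, each read away from the element on the
    element's own strand; duplicates (identical insertions) removed.

    ``annotations`` is an iterable with ``te_id``, ``start``, ``end`` and
    ``strand`` attributes (TEAnnotation or truth-table rows work).
    """
    flanks: list[JunctionFlank] = []
    for a in annotations:
        start, end, strand = int(a.start), int(a.end), getattr(a, "strand", "+")
        if not 0 <= start < end <= len(genome):
            logger.warning("boundary outside genome for %s; skipped", a.te_id)
            continue
        up = genome[max(0, start - flank):start]      # left of element, fwd
        down = genome[end:end + flank]                # right of element, fwd
        trunc_up = len(up) < flank
        trunc_down = len(down) < flank
        if strand == "+":
            pairs = [("IRl", revcomp(up), trunc_up), ("IRr", down, trunc_down)]
        else:
            pairs = [("IRl", down, trunc_down), ("IRr", revcomp(up), trunc_up)]
        for side, seq, trunc in pairs:
            flanks.append(JunctionFlank(te_id=str(a.te_id), side=side,
                                        sequence=seq, truncated=trunc))
    if dedup:
        seen: set[str] = set()
        unique = []
        for f in flanks:
            if f.dedup_key not in seen:
                seen.add(f.dedup_key)
                unique.append(f)
        flanks = unique
    return flanks


# ---------------------------------------------------------------------------
# Sigma-A promoter scanning
# ---------------------------------------------------------------------------

def build_pwm(consensus: str, pseudocount: float = 0.1,
              background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
              ) -> np.ndarray:
    """Consensus-seeded log-odds PWM (log2 vs background), one-hot counts
    plus ``pseudocount`` per base."""
    bg = np.asarray(background)
    pwm = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus.upper()):
        counts = np.full(4, pseudocount)
        counts[NT_INDEX[c]] += 1.0
        p = counts / counts.sum()
        pwm[i] = np.log2(p / bg)
    return pwm


def default_sigma_pwms() -> tuple[np.ndarray, np.ndarray]:
    """The canonical sigma-A box models: TTGACA (-35) and TATAAT (-10)."""
    return build_pwm("TTGACA"), build_pwm("TATAAT")


def _window_scores(seq_idx: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score of *pwm* at every start position of the encoded sequence."""
    L = pwm.shape[0]
    n = len(seq_idx) - L + 1
    if n <= 0:
        return np.zeros(0)
    out = np.zeros(n)
    for j in range(L):
        out += pwm[j, seq_idx[j:j + n]]
    return out


def scan_sigma_promoters(
    sequence: str,
    pwm35: np.ndarray | None = None,
    pwm10: np.ndarray | None = None,
    spacer_range: tuple[int, int] = (15, 19),
    score_min: float = 8.0,
    resolve_overlaps: bool = True,
) -> list[PromoterHit]:
    """Paired-PWM sigma-A promoter scan of one strand.

    For every -35 candidate, each spacer in ``spacer_range`` positions the
    -10 matrix; hits with combined log-odds >= ``score_min`` are kept, and
    overlapping hits are resolved best-score-first.
    """
    if pwm35 is None or pwm10 is None:
        d35, d10 = default_sigma_pwms()
        pwm35 = pwm35 if pwm35 is not None else d35
        pwm10 = pwm10 if pwm10 is not None else d10
    l35, l10 = pwm35.shape[0], pwm10.shape[0]
    lo, hi = spacer_range
    if len(sequence) < l35 + lo + l10:
        return []
    idx = np.asarray([NT_INDEX.get(c, 0) for c in sequence.upper()])
    s35 = _window_scores(idx, pwm35)
    s10 = _window_scores(idx, pwm10)
    raw: list[PromoterHit] = []
    for spacer in range(lo, hi + 1):
        shift = l35 + spacer
        n = min(len(s35), len(s10) - shift)
        if n <= 0:
            continue
        total = s35[:n] + s10[shift:shift + n]
        for p in np.nonzero(total >= score_min)[0]:
            raw.append(PromoterHit(pos_minus35=int(p), spacer=spacer,
                                   score=float(total[p])))
    if not resolve_overlaps:
        return sorted(raw, key=lambda h: h.pos_minus35)
    kept: list[PromoterHit] = []
    for h in sorted(raw, key=lambda h: (-h.score, h.pos_minus35, h.spacer)):
        h_end = h.pos_minus35 + l35 + h.spacer + l10
        clash = any(h.pos_minus35 < k.pos_minus35 + l35 + k.spacer + l10
                    and k.pos_minus35 < h_end for k in kept)
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: h.pos_minus35)


# ---------------------------------------------------------------------------
# Positional enrichment and orientation
# ---------------------------------------------------------------------------

def positional_enrichment(
    flank_hits: list[tuple[str, int]],
    n_junctions: int,
    horizon: int = 30,
) -> JunctionProfile:
    """The junction-relative promoter-detection profile.

    ``flank_hits`` are (side, offset) pairs, one per promoter hit, with
    ``offset`` the -35 box start relative to the junction.  Distances are
    signed: IRl-side negative, IRr-side positive.  ``r(d)`` is the fraction
    of all promoters within the horizon detected at distance d; the ratios
    sum to 1 whenever any promoter is found.
    """
    counts: dict[int, int] = {d: 0 for d in range(-horizon, horizon + 1)}
    total = 0
    for side, offset in flank_hits:
        if side not in ("IRl", "IRr"):
            raise ValueError(f"unknown side {side!r}")
        if offset < 0 or offset > horizon:
            continue
        d = offset if side == "IRr" else -offset
        counts[d] += 1
        total += 1
    if total == 0:
        logger.warning("no promoters within %d bp of any junction", horizon)
        ratios = {d: 0.0 for d in counts}
    else:
        ratios = {d: c / total for d, c in counts.items()}
    return JunctionProfile(ratios=ratios, n_promoters_total=total,
                           n_junctions=n_junctions, horizon=horizon)


def profile_from_flanks(
    flanks: list[JunctionFlank],
    horizon: int = 30,
    **scan_kwargs,
) -> JunctionProfile:
    """Scan every flank and accumulate the positional enrichment profile."""
    hits = []
    for f in flanks:
        for h in scan_sigma_promoters(f.sequence, **scan_kwargs):
            hits.append((f.side, h.pos_minus35))
    return positional_enrichment(hits, n_junctions=len(flanks), horizon=horizon)


def orientation_bias(
    per_te_hits: dict[str, list[tuple[str, int]]],
    horizon: int = 30,
) -> tuple[float | None, dict[str, bool]]:
    """Fraction of elements whose IRr faces the nearest detected promoter.

    ``per_te_hits`` maps each element to its (side, offset) promoter hits.
    Elements with no promoter within the horizon are skipped; returns
    (fraction or None when undefined, per-element IRr-facing verdicts).
    """
    verdicts: dict[str, bool] = {}
    for te_id, hits in per_te_hits.items():
        within = [(side, off) for side, off in hits if 0 <= off <= horizon]
        if not within:
            continue
        side, _ = min(within, key=lambda t: (t[1], t[0] != "IRr"))
        verdicts[te_id] = side == "IRr"
    if not verdicts:
        return None, {}
    frac = sum(verdicts.values()) / len(verdicts)
    return frac, verdicts


# ---------------------------------------------------------------------------
# DR consensus
# ---------------------------------------------------------------------------

def dr_consensus(dr_sequences: list[str],
                 min_frequency: float = 0.25) -> tuple[str, pd.DataFrame]:
    """IUPAC consensus and position frequency matrix of equal-length DRs.

    The consensus letter at each position is the IUPAC code covering every
    base whose frequency reaches ``min_frequency`` (N when all four
    qualify).  Mixed input lengths should be grouped by the caller.
    """
    if not dr_sequences:
        raise ValueError("no DR sequences")
    lengths = {len(s) for s in dr_sequences}
    if len(lengths) != 1:
        raise ValueError("DR sequences must have equal length; group by length")
    L = lengths.pop()
    counts = np.zeros((L, 4))
    for s in dr_sequences:
        for i, c in enumerate(s.upper()):
            if c in NT_INDEX:
                counts[i, NT_INDEX[c]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    letters = []
    for i in range(L):
        bases = frozenset(NT[j] for j in range(4) if freqs[i, j] >= min_frequency)
        if not bases:
            bases = frozenset(NT[int(np.argmax(freqs[i]))])
        letters.append(_IUPAC_OF[bases])
    pfm = pd.DataFrame(freqs, columns=list(NT))
    pfm.index.name = "position"
    return "".join(letters), pfm


def write_pfm(pfm: pd.DataFrame, path, name: str = "motif") -> None:
    """Plain-text PFM in a MEME-like format (one row per position)."""
    with open(path, "w") as fh:
        fh.write(f"# PFM {name}\n# columns: {' '.join(NT)}\n")
        for _, row in pfm.iterrows():
            fh.write(" ".join(f"{row[c]:.4f}" for c in NT) + "\n")
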