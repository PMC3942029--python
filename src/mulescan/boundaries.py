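"""TE boundary calling from multi-copy genomic evidence.

Workflow: the transposase CDS is extracted with 400 bp of flanking sequence
and mapped back to the genome; when enough copies exist (>3 hits), the modal
start/end of the high-scoring segment pairs give the element boundaries; if
hits reach the window edges the window is extended until the element's
extremities fall inside it.  Boundaries are then validated and refined by
terminal inverted-repeat (IR) detection (18-39 bp, conserved terminal C) and
direct-repeat (DR, 8-9 bp target-site duplication) detection, and the
transposase gene is checked for the two-ORF/-1 programmed frameshift
organization seen in some IS groups.

Genomic mapping at desk scale uses an internal seed-and-extend nucleotide
aligner (k=12 exact seeds, x-drop ungapped extension trimmed to the maximal
scoring segment); precomputed 12-column tabular hit tables can be used as a
drop-in replacement.

Coordinates are 0-based half-open throughout; GFF3 output is 1-based
inclusive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqs import revcomp

logger = logging.getLogger(__name__)

STOPS = {"TAA", "TAG", "TGA"}


class InsufficientCopiesError(Exception):
    """Too few genomic hits for automatic boundary calling; the caller should
    fall back to related isolates of the same species."""


@dataclass(frozen=True)
class GenomicHit:
    """One nucleotide HSP; subject coordinates are always forward-strand."""

    query_id: str
    genome_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float

    def __post_init__(self):
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("starts must precede ends")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class IRPair:
    """A terminal inverted-repeat pair (coordinates on the scanned record)."""

    left: tuple[int, int, str]
    right: tuple[int, int, str]
    mismatches: int


@dataclass(frozen=True)
class DirectRepeat:
    length: int
    left_seq: str
    right_seq: str


@dataclass
class TEAnnotation:
    """One called element."""

    te_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"
    ir: IRPair | None = None
    dr: DirectRepeat | None = None
    copy_count: int = 0
    frameshift: bool = False
    fs_junction: int | None = None
    family_id: str | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Seed-and-extend nucleotide mapping
# ---------------------------------------------------------------------------

_NT4 = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_nt(seq: str) -> np.ndarray:
    return np.asarray([_NT4.get(c, 0) for c in seq.upper()], dtype=np.int8)


def _xdrop_extend(q: np.ndarray, s: np.ndarray, qi: int, si: int, k: int,
                  match: int, mismatch: int, xdrop: int) -> tuple[int, int, int]:
    """Extend a k-base seed at (qi, si) on its diagonal in both directions;
    each side is trimmed to its maximal-scoring segment (x-drop explores,
    argmax trims).  Returns (left_ext, right_ext, extension_score)."""

    def one_side(qa, sa):
        n = min(len(qa), len(sa))
        if n == 0:
            return 0, 0
        eq = qa[:n] == sa[:n]
        step = np.where(eq, match, mismatch)
        cum = np.cumsum(step)
        runmax = np.maximum.accumulate(cum)
        bad = np.nonzero(runmax - cum > xdrop)[0]
        cut = bad[0] if len(bad) else n
        if cut == 0 or cum[:cut].max() <= 0:
            return 0, 0
        best = int(np.argmax(cum[:cut])) + 1
        return best, int(cum[best - 1])

    right_len, right_score = one_side(q[qi + k:], s[si + k:])
    left_len, left_score = one_side(q[:qi][::-1], s[:si][::-1])
    return left_len, right_len, left_score + right_score


def seed_extend_hits(
    query: str,
    genome: str,
    query_id: str = "query",
    genome_id: str = "genome",
    k: int = 12,
    match: int = 1,
    mismatch: int = -3,
    xdrop: int = 20,
    min_score: int = 40,
    seed_step: int = 4,
) -> list[GenomicHit]:
    """Map *query* onto *genome* on both strands.

    Exact k-mer seeds (sampled every ``seed_step`` query positions) are
    extended ungapped with an x-drop, trimmed to the maximal-scoring
    segment; overlapping extensions on one diagonal are reported once.
    """
    genome_enc = _encode_nt(genome)
    index: dict[str, list[int]] = {}
    for i in range(0, len(genome) - k + 1):
        index.setdefault(genome[i:i + k], []).append(i)

    hits: list[GenomicHit] = []
    for strand in "+-":
        qseq = query if strand == "+" else revcomp(query)
        q_enc = _encode_nt(qseq)
        covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> q spans
        for qi in range(0, len(qseq) - k + 1, seed_step):
            kmer = qseq[qi:qi + k]
            for si in index.get(kmer, ()):
                diag = si - qi
                spans = covered.get(diag, [])
                if any(a <= qi < b for a, b in spans):
                    continue
                lext, rext, score = _xdrop_extend(q_enc, genome_enc, qi, si, k,
                                                  match, mismatch, xdrop)
                score += k * match  # seed itself
                qs, qe = qi - lext, qi + k + rext
                ss, se = si - lext, si + k + rext
                covered.setdefault(diag, []).append((qs, qe))
                if score < min_score:
                    continue
                ident = 100.0 * float(
                    (q_enc[qs:qe] == genome_enc[ss:se]).mean())
                if strand == "+":
                    q0, q1 = qs, qe
                else:
                    q0, q1 = len(qseq) - qe, len(qseq) - qs
                hits.append(GenomicHit(query_id, genome_id, q0, q1, ss, se,
                                       strand, ident))
    # deduplicate identical segments found from different seeds
    seen = set()
    out = []
    for h in sorted(hits, key=lambda h: (h.s_start, h.s_end, h.strand)):
        key = (h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Boundary determination
# ---------------------------------------------------------------------------

@dataclass
class FlankedRecord:
    """A sub-sequence with coordinate bookkeeping back to its genome."""

    sequence: str
    offset: int  # genome position of sequence[0]
    truncated_left: bool = False
    truncated_right: bool = False

    def to_genome(self, pos: int) -> int:
        return pos + self.offset


def extract_with_flanks(genome: str, cds_start: int, cds_end: int,
                        flank: int = 400) -> FlankedRecord:
    """Extract ``[cds_start - flank, cds_end + flank)``, truncating (with a
    flag) at contig ends."""
    if not 0 <= cds_start < cds_end <= len(genome):
        raise ValueError("CDS coordinates outside genome")
    s = cds_start - flank
    e = cds_end + flank
    trunc_l = s < 0
    trunc_r = e > len(genome)
    s = max(0, s)
    e = min(len(genome), e)
    return FlankedRecord(genome[s:e], offset=s,
                         truncated_left=trunc_l, truncated_right=trunc_r)


def majority_boundaries(hits: list[GenomicHit],
                        min_copies: int = 3) -> tuple[int, int]:
    """Modal HSP start and end in query coordinates.

    Requires strictly more than ``min_copies`` hits (the automatic-calling
    rule); otherwise :class:`InsufficientCopiesError` signals the caller to
    consult related isolates.  Modal ties resolve to the smaller start and
    the larger end (maximal element).
    """
    if not hits:
        raise ValueError("no hits")
    if len({h.query_id for h in hits}) != 1:
        raise ValueError("hits must share one query")
    if len(hits) <= min_copies:
        raise InsufficientCopiesError(
            f"{len(hits)} hits <= min_copies={min_copies}")
    start_counts = Counter(h.q_start for h in hits)
    end_counts = Counter(h.q_end for h in hits)
    top_s = max(start_counts.values())
    top_e = max(end_counts.values())
    start = min(v for v, c in start_counts.items() if c == top_s)
    end = max(v for v, c in end_counts.items() if c == top_e)
    return start, end


def extend_boundaries(
    genome: str,
    cds_start: int,
    cds_end: int,
    *,
    flank: int = 400,
    flank_step: int = 400,
    max_flank: int = 8000,
    min_copies: int = 3,
    genome_id: str = "genome",
    **map_kwargs,
) -> tuple[int, int, int, list[str]]:
    """Iteratively widen the extraction window until the majority boundaries
    fall strictly inside it (large elements reach the initial window edges).

    Returns (start, end, copy_count, flags) in genome coordinates.  The
    element's own genomic copy is excluded from the vote.
    """
    flags: list[str] = []
    current = flank
    while True:
        rec = extract_with_flanks(genome, cds_start, cds_end, current)
        hits = seed_extend_hits(rec.sequence, genome, genome_id=genome_id,
                                **map_kwargs)
        own_s, own_e = rec.offset, rec.offset + len(rec.sequence)
        ext = [h for h in hits if not (h.s_start < own_e and h.s_end > own_s)]
        if not ext:
            raise InsufficientCopiesError("no non-self hits")
        qs, qe = majority_boundaries(ext, min_copies=min_copies)
        interior = qs > 0 and qe < len(rec.sequence)
        at_contig_edge = (rec.truncated_left and qs == 0) or \
                         (rec.truncated_right and qe == len(rec.sequence))
        if interior or current >= max_flank or at_contig_edge:
            if not interior:
                flags.append("window_truncated")
            copies = len({(h.s_start, h.s_end) for h in ext})
            return rec.to_genome(qs), rec.to_genome(qe), copies, flags
        current += flank_step


# ---------------------------------------------------------------------------
# IR / DR / frameshift validation
# ---------------------------------------------------------------------------

def ranked_inverted_repeats(
    seq: str,
    search_window: int = 60,
    min_len: int = 18,
    max_len: int = 39,
    max_mismatch_frac: float = 0.17,
    require_terminal_c: bool = True,
    top_n: int = 20,
) -> list[IRPair]:
    """Candidate terminal inverted-repeat pairs of a record, best first.

    The two terminal windows are scanned for reverse-complement match pairs
    (score = matches - mismatches) within the length bounds and mismatch
    tolerance.  With ``require_terminal_c`` each IR must end in C read
    outward on its own strand, i.e. the left segment starts with G and the
    right segment ends with C on the forward strand.  Ranking is by score,
    then fewer mismatches, then longer, then more terminal repeats.
    """
    n = len(seq)
    w = min(search_window, n // 2)
    if w < min_len:
        return []
    seq = seq.upper()
    left = seq[:w]
    rc_right = revcomp(seq[n - w:])  # rc_right[m] pairs with seq[n-1-m]
    la = np.frombuffer(left.encode(), dtype="S1")
    ra = np.frombuffer(rc_right.encode(), dtype="S1")

    cands = []  # (score, -mm, L, -i, -m)
    for L in range(min(max_len, w), min_len - 1, -1):
        lw = sliding_window_view(la, L)   # lw[i] = left[i:i+L]
        rw = sliding_window_view(ra, L)   # rw[m] = rc_right[m:m+L]
        if require_terminal_c:
            li = np.nonzero(lw[:, 0] == b"G")[0]
            ri = np.nonzero(rw[:, 0] == b"G")[0]
        else:
            li = np.arange(lw.shape[0])
            ri = np.arange(rw.shape[0])
        if len(li) == 0 or len(ri) == 0:
            continue
        mism = L - (lw[li, None, :] == rw[None, ri, :]).sum(axis=2)
        max_mm = int(max_mismatch_frac * L)
        ok = np.nonzero(mism <= max_mm)
        for a, b in zip(*ok):
            i, m = int(li[a]), int(ri[b])
            mm = int(mism[a, b])
            cands.append((L - 2 * mm, -mm, L, -i, -m))
    cands.sort(reverse=True)
    out = []
    for score, nmm, L, ni, nm in cands[:top_n]:
        i, m, mm = -ni, -nm, -nmm
        right_start = n - m - L
        out.append(IRPair(
            left=(i, i + L, seq[i:i + L]),
            right=(right_start, right_start + L, seq[right_start:right_start + L]),
            mismatches=mm))
    return out


def find_inverted_repeats(
    seq: str,
    search_window: int = 60,
    min_len: int = 18,
    max_len: int = 39,
    max_mismatch_frac: float = 0.17,
    require_terminal_c: bool = True,
) -> IRPair | None:
    """The single best IR pair of a record (see
    :func:`ranked_inverted_repeats`), or ``None`` when nothing qualifies."""
    cands = ranked_inverted_repeats(
        seq, search_window=search_window, min_len=min_len, max_len=max_len,
        max_mismatch_frac=max_mismatch_frac,
        require_terminal_c=require_terminal_c, top_n=1)
    return cands[0] if cands else None


def detect_dr(genome: str, start: int, end: int,
              lengths: tuple[int, ...] = (8, 9),
              max_mismatch: int = 0) -> DirectRepeat | None:
    """Target-site duplication flanking ``[start, end)``: the left-flank
    suffix must equal the right-flank prefix (exact by default); the longest
    matching length wins."""
    for L in sorted(lengths, reverse=True):
        if start - L < 0 or end + L > len(genome):
            continue
        left = genome[start - L:start]
        right = genome[end:end + L]
        mm = sum(a != b for a, b in zip(left, right))
        if mm <= max_mismatch:
            return DirectRepeat(L, left, right)
    return None


def ir_complementarity(ir_left_seq: str, ir_right_seq: str) -> float:
    """Percent complementarity: global alignment of the left IR against the
    reverse complement of the right IR; 100 x matches / aligned columns."""
    if not ir_left_seq or not ir_right_seq:
        raise ValueError("empty IR sequence")
    from Bio.Align import PairwiseAligner
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(ir_left_seq.upper(), revcomp(ir_right_seq.upper()))[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    return 100.0 * c.identities / columns if columns else 0.0


def find_orfs(seq: str, min_aa: int = 80) -> list[tuple[int, int, str]]:
    """Simple ORF scan (stop-to-stop spans starting at the first ATG), both
    strands; coordinates on the forward strand of *seq*."""
    orfs = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        for frame in range(3):
            pos = frame
            region_start = frame
            while pos + 3 <= n:
                if s[pos:pos + 3] in STOPS:
                    _add_orf(orfs, s, region_start, pos + 3, strand, n, min_aa)
                    region_start = pos + 3
                pos += 3
            _add_orf(orfs, s, region_start, pos, strand, n, min_aa, open_end=True)
    return sorted(orfs)


def _add_orf(orfs, s, region_start, region_end, strand, n, min_aa,
             open_end=False):
    atg = s.find("ATG", region_start, region_end - 2)
    while atg != -1 and (atg - region_start) % 3 != 0:
        atg = s.find("ATG", atg + 1, region_end - 2)
    if atg == -1:
        return
    if (region_end - atg) // 3 - (0 if open_end else 1) < min_aa:
        return
    if strand == "+":
        orfs.append((atg, region_end, "+"))
    else:
        orfs.append((n - region_end, n - atg, "-"))


def detect_minus1_frameshift(
    seq: str,
    orfs: list[tuple[int, int]] | list[tuple[int, int, str]],
) -> tuple[bool, int | None]:
    """Detect the two-ORF organization where a single -1 ribosomal slip in
    the overlap restores one contiguous stop-free reading through both ORFs.

    ``orfs`` are same-strand (start, end) spans on *seq* (an optional third
    strand element is accepted and must agree).  Returns (found, junction),
    the junction being the frame-0 position of the slip.
    """
    spans = []
    for o in orfs:
        if len(o) >= 3 and o[2] not in ("+", None):
            return False, None  # mixed/minus strands not comparable here
        spans.append((o[0], o[1]))
    spans.sort()
    if len(spans) < 2:
        return False, None
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if c >= b:           # disjoint: no overlap to slip within
            continue
        if (c - a) % 3 != 2:  # downstream ORF must sit in the -1 frame
            continue
        lo = max(a + 3, c + 1)
        lo += (-(lo - a)) % 3  # align candidate slips to ORF1 codon frame
        for s_pos in range(lo, min(b, d) + 1, 3):
            if _stop_free(seq, s_pos - 1, d):
                return True, s_pos
    return False, None


def _stop_free(seq: str, start: int, end: int) -> bool:
    for p in range(start, end - 5, 3):  # allow terminal stop codon
        if seq[p:p + 3] in STOPS:
            return False
    return True


# ---------------------------------------------------------------------------
# Full per-element annotation
# ---------------------------------------------------------------------------

def annotate_element(
    genome: str,
    cds_start: int,
    cds_end: int,
    *,
    te_id: str = "TE",
    genome_id: str = "genome",
    flank: int = 400,
    min_copies: int = 3,
    ir_margin: int = 12,
    ir_kwargs: dict | None = None,
    dr_lengths: tuple[int, ...] = (8, 9),
    family_id: str | None = None,
    **map_kwargs,
) -> TEAnnotation:
    """Call and validate one element starting from its transposase CDS.

    Majority/extension boundary calling, then joint IR/DR validation: among
    the ranked IR candidates on the called span (+/- a small margin), the
    best one whose implied boundaries are also flanked by an exact direct
    repeat wins (boundaries are refined to its extremities); without any
    DR-supported candidate the best-scoring IR alone refines the
    boundaries.  Frameshift analysis follows on the refined element.
    """
    start, end, copies, flags = extend_boundaries(
        genome, cds_start, cds_end, flank=flank, min_copies=min_copies,
        genome_id=genome_id, **map_kwargs)

    ir_kwargs = dict(ir_kwargs or {})
    window = ir_kwargs.pop("search_window", 60)
    rec_s = max(0, start - ir_margin)
    rec_e = min(len(genome), end + ir_margin)
    cands = ranked_inverted_repeats(genome[rec_s:rec_e],
                                    search_window=window + ir_margin,
                                    **ir_kwargs)
    ir = None
    dr = None
    for cand in cands:
        d = detect_dr(genome, rec_s + cand.left[0], rec_s + cand.right[1],
                      lengths=dr_lengths)
        if d is not None:
            ir, dr = cand, d
            break
    if ir is None and cands:
        ir = cands[0]
    if ir is not None:
        start = rec_s + ir.left[0]
        end = rec_s + ir.right[1]
        ir = IRPair(left=(rec_s + ir.left[0], rec_s + ir.left[1], ir.left[2]),
                    right=(rec_s + ir.right[0], rec_s + ir.right[1], ir.right[2]),
                    mismatches=ir.mismatches)
    else:
        flags.append("no_ir")

    if dr is None:
        dr = detect_dr(genome, start, end, lengths=dr_lengths)
    elem = genome[start:end]
    fs, junction = False, None
    for variant in (elem, revcomp(elem)):
        orfs = [(a, b) for a, b, st in find_orfs(variant) if st == "+"]
        fs, junction = detect_minus1_frameshift(variant, orfs)
        if fs:
            break
    return TEAnnotation(te_id=te_id, genome_id=genome_id, start=start,
                        end=end, ir=ir, dr=dr, copy_count=copies,
                        frameshift=fs, fs_junction=junction,
                        family_id=family_id, flags=flags)


def write_annotations_gff3(annotations: list[TEAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = [f"ID={a.te_id}", f"copy_count={a.copy_count}",
                     f"frameshift={str(a.frameshift).lower()}"]
            if a.family_id:
                attrs.append(f"family={a.family_id}")
            if a.dr:
                attrs.append(f"dr_length={a.dr.length}")
            fh.write("\t".join([
                a.genome_id, "mulescan", "mobile_genetic_element",
                str(a.start + 1), str(a.end), ".", a.strand, ".",
                ";".join(attrs)]) + "\n")


def write_annotations_tsv(annotations: list[TEAnnotation], path) -> None:
    import pandas as pd
    rows = []
    for a in annotations:
        rows.append({
            "te_id": a.te_id, "genome_id": a.genome_id, "start": a.start,
            "end": a.end, "strand": a.strand, "copy_count": a.copy_count,
            "ir_left": a.ir.left[2] if a.ir else None,
            "ir_right": a.ir.right[2] if a.ir else None,
            "ir_mismatches": a.ir.mismatches if a.ir else None,
            "dr_length": a.dr.length if a.dr else None,
            "dr_sequence": a.dr.left_seq if a.dr else None,
            "frameshift": a.frameshift, "family_id": a.family_id,
            "flags": ",".join(a.flags),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
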