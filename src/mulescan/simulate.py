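"""Synthetic data generation with ground truth.

This module emulates the data a comparative survey of prokaryotic
Mutator-like transposases (p-MULTs) works from, so every downstream stage can
be exercised against known truth:

* **protein families** diverged from ancestral transposases at configurable
  substitution rates, with the DDE catalytic triad, the C/D(2)H signature and
  two N-terminal anchor blocks (N1, N2) held invariant;
* **genomes** carrying multi-copy transposable elements (TEs) bounded by
  terminal inverted repeats (IRs, 18-39 bp) whose insertion duplicates the
  8-9 bp target site (direct repeats, DRs);
* **insertion-site biases**: fixed-offset placement upstream of sigma-A
  promoters (the Tn*GBS*/IS*Kra4*-style model), AT-rich 8-mer target sites
  (the IS*H6*-style model, default motif ``AANATNTT``), or uniform-random
  placement (IS*256*/ICE-style).

Orientation convention: an element in canonical orientation reads ``G ... C``
on the top strand, i.e. each IR terminates in a C when read on its own strand
pointing away from the element (bottom strand at the left end, top strand at
the right end).  ``ir_left`` and ``ir_right`` are both stored as top-strand
sequences, so ``ir_right`` is approximately the reverse complement of
``ir_left``.

All generators are deterministic for a fixed seed.  Truth coordinates are
0-based half-open on the emitted genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import iupac_regex, matches_iupac, random_nt, revcomp

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: sense codons per amino acid (standard code, stop codons excluded)
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic transposase family.

    ``triad_positions`` are the 0-based indices of the catalytic D1, D2 and E
    residues in the ungapped ancestor; ``cdh_offset`` places the C/D(2)H
    signature (``[CD] x x H``) that many aa downstream of D2 (must lie in
    11-19); the segment between D2 and E is the alpha-helical insert and must
    span 99-138 aa.  ``anchor_blocks`` are the N-terminal conserved blocks
    (N1, N2); ``extra_conserved_blocks`` lets callers plant additional
    invariant segments (e.g. a promoter-targeting signature between N1 and
    N2).  ``root_divergence``, when set, derives this family's ancestor from
    a shared root sequence so families are transitively related;
    ``root_exempt`` additionally shields the conserved blocks during that
    root-level divergence (superfamily-wide conservation, as opposed to the
    default family-level conservation).  The catalytic letters (D, D, E and
    the C/D(2)H motif) are replanted in every ancestor regardless.
    """

    family_id: str
    n_members: int
    ancestor_length: int = 320
    substitution_rate: float = 0.25
    triad_positions: tuple[int, int, int] = (100, 170, 280)
    cdh_offset: int = 14
    anchor_blocks: tuple[tuple[int, int], ...] = ((10, 18), (28, 44))
    extra_conserved_blocks: tuple[tuple[int, int], ...] = ()
    root_divergence: float | None = None
    root_exempt: bool = False
    indel_rate: float = 0.0

    @property
    def insert_length(self) -> int:
        """Distance in aa between D2 and E."""
        return self.triad_positions[2] - self.triad_positions[1]

    def validate(self) -> None:
        d1, d2, e = self.triad_positions
        if not (0 <= d1 < d2 < e < self.ancestor_length):
            raise ValueError("triad positions must be strictly increasing and in range")
        if not 11 <= self.cdh_offset <= 19:
            raise ValueError("cdh_offset must lie in [11, 19]")
        if not 99 <= self.insert_length <= 138:
            raise ValueError("D2->E insert length must lie in [99, 138]")
        if d2 + self.cdh_offset + 3 >= e:
            raise ValueError("C/D(2)H motif must fall inside the D2->E insert")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        blocks = sorted(self.anchor_blocks + self.extra_conserved_blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError("overlapping conserved blocks")
        for s, e2 in blocks:
            if not 0 <= s < e2 <= self.ancestor_length:
                raise ValueError("conserved block outside ancestor")

    def exempt_positions(self) -> frozenset[int]:
        """Residue indices exempt from substitution (triad, C/D(2)H, anchors)."""
        d1, d2, e = self.triad_positions
        pos = {d1, d2, e}
        pos.update(range(d2 + self.cdh_offset, d2 + self.cdh_offset + 4))
        for s, t in self.anchor_blocks + self.extra_conserved_blocks:
            pos.update(range(s, t))
        return frozenset(pos)


@dataclass
class FamilyTruth:
    """Ground truth for a generated protein set."""

    specs: dict[str, FamilySpec]
    ancestors: dict[str, str]
    members: dict[str, str]  # member id -> family id
    root: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid, fid in self.members.items():
            spec = self.specs[fid]
            d1, d2, e = spec.triad_positions
            rows.append({"member_id": mid, "family_id": fid, "d1": d1, "d2": d2,
                         "e": e, "cdh_offset": spec.cdh_offset})
        return pd.DataFrame(rows)


def _mutate_protein(seq: str, rate: float, exempt: frozenset[int],
                    rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    for i in np.nonzero(mask)[0]:
        if int(i) in exempt:
            continue
        current = arr[i].decode()
        choices = [a for a in AA20 if a != current]
        arr[i] = rng.choice(choices).encode()
    out = arr.tobytes().decode()
    if indel_rate > 0.0:
        chars = []
        for i, c in enumerate(out):
            if i not in exempt and rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                chars.append(rng.choice(list(AA20)))
            chars.append(c)
        out = "".join(chars)
    return out


def _random_ancestor(spec: FamilySpec, rng: np.random.Generator,
                     base: str | None = None) -> str:
    if base is not None:
        if len(base) != spec.ancestor_length:
            raise ValueError("shared root length must match ancestor_length")
        # conserved blocks survive the root->ancestor divergence only when
        # the spec marks them as superfamily-wide (root_exempt); the
        # catalytic letters below are always replanted
        exempt = spec.exempt_positions() if spec.root_exempt else frozenset()
        seq = list(_mutate_protein(base, spec.root_divergence or 0.0,
                                   exempt, rng))
    else:
        seq = list(rng.choice(list(AA20), size=spec.ancestor_length))
    d1, d2, e = spec.triad_positions
    seq[d1] = "D"
    seq[d2] = "D"
    seq[e] = "E"
    cdh = d2 + spec.cdh_offset
    seq[cdh] = "C" if rng.random() < 0.5 else "D"
    seq[cdh + 3] = "H"
    return "".join(seq)


def generate_protein_families(
    specs: Sequence[FamilySpec],
    seed: int,
    root: str | None = None,
) -> tuple[list[SeqRecord], FamilyTruth]:
    """Generate protein families by i.i.d. per-site substitution from per-family
    ancestors.

    Each family descends from one ancestor; the catalytic triad (D, D, E),
    the C/D(2)H letters and the anchor blocks are exempt from substitution.
    Families whose spec sets ``root_divergence`` share a common root (passed
    in or generated once from the first such spec), which makes them
    transitively related -- the regime a cascade homology search exploits.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        spec.validate()
    if len({s.family_id for s in specs}) != len(specs):
        raise ValueError("duplicate family ids")

    rooted = [s for s in specs if s.root_divergence is not None]
    if rooted and root is None:
        root = _random_ancestor(rooted[0], rng)

    records: list[SeqRecord] = []
    truth = FamilyTruth(specs={s.family_id: s for s in specs},
                        ancestors={}, members={}, root=root)
    for spec in specs:
        base = root if spec.root_divergence is not None else None
        ancestor = _random_ancestor(spec, rng, base=base)
        truth.ancestors[spec.family_id] = ancestor
        exempt = spec.exempt_positions()
        for i in range(spec.n_members):
            member = _mutate_protein(ancestor, spec.substitution_rate, exempt,
                                     rng, spec.indel_rate)
            mid = f"{spec.family_id}_m{i:02d}"
            records.append(SeqRecord(Seq(member), id=mid, description=""))
            truth.members[mid] = spec.family_id
    return records, truth


# ---------------------------------------------------------------------------
# Planted transposable elements
# ---------------------------------------------------------------------------

@dataclass
class PlantedTE:
    """One synthetic element in canonical (``G ... C``) orientation.

    ``orfs`` are (start, end) 0-based half-open coordinates of the
    transposase ORF(s) relative to ``sequence``; for a frameshift-split
    element there are two overlapping ORFs and ``fs_junction`` records the
    frame-0 position where a -1 ribosomal slip restores the full product.
    """

    te_id: str
    family_id: str
    ir_left: str
    ir_right: str
    dr_length: int
    transposase_cds: str
    passenger_genes: tuple[str, ...] = ()
    frameshift_split: bool = False
    sequence: str = ""
    cds_start: int = 0
    cds_end: int = 0
    orfs: tuple[tuple[int, int], ...] = ()
    fs_junction: int | None = None

    def validate(self, min_complementarity: float = 0.83) -> None:
        for ir in (self.ir_left, self.ir_right):
            if not 18 <= len(ir) <= 39:
                raise ValueError("IR length must lie in [18, 39]")
        if self.ir_left[0] != "G" or self.ir_right[-1] != "C":
            raise ValueError("element must read G ... C (terminal C rule)")
        rc = revcomp(self.ir_left)
        n = min(len(rc), len(self.ir_right))
        ident = sum(a == b for a, b in zip(rc[:n], self.ir_right[:n])) / n
        if ident < min_complementarity:
            raise ValueError(
                f"IR complementarity {ident:.2f} below {min_complementarity}")
        if self.dr_length not in (8, 9):
            raise ValueError("dr_length must be 8 or 9")


def _protein_to_cds(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(CODONS[a]) for a in protein)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _frameshift_cds(protein: str, rng: np.random.Generator):
    """Encode *protein* as two ORFs whose overlap restores the full product
    under a -1 ribosomal frameshift.

    The DNA carries codons for ``protein[:k]`` in frame 0; the codons for
    ``protein[k:]`` start one base earlier than the frame-0 boundary (frame
    -1), sharing that base.  Returns (dna, orf1, orf2, junction).
    """
    n = len(protein)
    order = sorted(range(1, n - 1), key=lambda k: abs(k - n // 2))
    for k in order:
        c1_opts = CODONS[protein[k - 1]]
        c2_opts = CODONS[protein[k]]
        pairs = [(c1, c2) for c1 in c1_opts for c2 in c2_opts if c1[2] == c2[0]]
        if pairs:
            break
    else:  # pragma: no cover - always satisfiable with 20-aa alphabet
        raise ValueError("no compatible codon pair for frameshift junction")
    c1, c2 = pairs[rng.integers(len(pairs))]
    front = "".join(rng.choice(CODONS[a]) for a in protein[: k - 1]) + c1
    back = c2 + "".join(rng.choice(CODONS[a]) for a in protein[k + 1:]) + "TAA"
    dna = front + back[1:]
    slip = 3 * k  # frame-0 codon boundary where the -1 slip occurs
    # ORF1: frame-0 reading up to (and including) the first downstream stop
    e1 = None
    for p in range(slip, len(dna) - 2, 3):
        if dna[p:p + 3] in STOPS:
            e1 = p + 3
            break
    if e1 is None:
        dna += "TAA"[: 3 - len(dna) % 3 if len(dna) % 3 else 0]
        e1 = len(dna) - len(dna) % 3
    orf1 = (0, e1)
    orf2 = (slip - 1, slip - 1 + len(back))
    return dna, orf1, orf2, slip


def make_planted_te(
    te_id: str,
    rng: np.random.Generator,
    *,
    family_id: str | None = None,
    ir_length: int = 24,
    complementarity: float = 1.0,
    cds_protein: str | None = None,
    cds_aa_length: int = 300,
    dr_length: int = 9,
    n_passengers: int = 0,
    passenger_length: int = 600,
    frameshift_split: bool = False,
    pad: int = 40,
    gc: float = 0.40,
) -> PlantedTE:
    """Assemble one synthetic element: left IR, padding, transposase CDS,
    optional passenger genes, padding, right IR.

    ``complementarity`` sets the reverse-complement identity between the two
    IRs (0.83-1.0); mismatches are placed at interior IR positions so the
    terminal-C rule always holds.
    """
    if not 18 <= ir_length <= 39:
        raise ValueError("ir_length must lie in [18, 39]")
    if not 0.83 <= complementarity <= 1.0:
        raise ValueError("complementarity must lie in [0.83, 1.0]")
    ir_left = "G" + random_nt(rng, ir_length - 1, gc=0.5)
    ir_right = list(revcomp(ir_left))  # ends in C
    n_mut = round((1.0 - complementarity) * ir_length)
    if n_mut:
        positions = rng.choice(np.arange(1, ir_length - 1), size=n_mut,
                               replace=False)
        for p in positions:
            cur = ir_right[p]
            ir_right[p] = rng.choice([b for b in "ACGT" if b != cur])
    ir_right = "".join(ir_right)

    protein = cds_protein if cds_protein is not None else _random_protein(rng, cds_aa_length)
    if frameshift_split:
        cds, orf1, orf2, slip = _frameshift_cds(protein, rng)
    else:
        cds = _protein_to_cds(protein, rng) + "TAA"
        orf1, orf2, slip = (0, len(cds)), None, None

    passengers = tuple(_protein_to_cds(_random_protein(rng, passenger_length // 3), rng) + "TAA"
                       for _ in range(n_passengers))

    parts = [ir_left, random_nt(rng, pad, gc)]
    cds_start = sum(len(p) for p in parts)
    parts.append(cds)
    cds_end = cds_start + len(cds)
    for pg in passengers:
        parts.append(random_nt(rng, pad, gc))
        parts.append(pg)
    parts.append(random_nt(rng, pad, gc))
    parts.append(ir_right)
    sequence = "".join(parts)

    orfs = [(cds_start + orf1[0], cds_start + orf1[1])]
    if orf2 is not None:
        orfs.append((cds_start + orf2[0], cds_start + orf2[1]))
    te = PlantedTE(
        te_id=te_id,
        family_id=family_id or te_id,
        ir_left=ir_left,
        ir_right=ir_right,
        dr_length=dr_length,
        transposase_cds=cds,
        passenger_genes=passengers,
        frameshift_split=frameshift_split,
        sequence=sequence,
        cds_start=cds_start,
        cds_end=cds_end,
        orfs=tuple(orfs),
        fs_junction=None if slip is None else cds_start + slip,
    )
    te.validate(min_complementarity=min(0.83, complementarity))
    return te


# ---------------------------------------------------------------------------
# Site models and genome planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteModel:
    """Where and how elements insert.

    * ``promoter_offset``: a sigma-A promoter is written next to the IRr-genome
      junction with the -35 box at a sampled distance (default mass on
      15/16/17 bp, mode 16 -- the Tn*GBS* geometry); ``orientation_rule``
      controls whether IRr always faces the promoter.
    * ``at_rich_motif``: insertion only at genomic matches of an IUPAC motif
      (default ``AANATNTT``), which then becomes the duplicated target site.
    * ``uniform``: unbiased placement.
    """

    kind: str = "uniform"
    offset_distribution: Mapping[int, float] = field(
        default_factory=lambda: {15: 0.25, 16: 0.5, 17: 0.25})
    motif: str = "AANATNTT"
    orientation_rule: str = "irr_toward_promoter"
    spacer_range: tuple[int, int] = (15, 19)
    box35: str = "TTGACA"
    box10: str = "TATAAT"
    corruption: float = 0.1

    def validate(self, dr_length: int | None = None) -> None:
        if self.kind not in {"promoter_offset", "at_rich_motif", "uniform"}:
            raise ValueError(f"unknown site model kind: {self.kind}")
        if self.orientation_rule not in {"irr_toward_promoter", "unbiased"}:
            raise ValueError(f"unknown orientation rule: {self.orientation_rule}")
        if self.kind == "promoter_offset":
            total = sum(self.offset_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("offset probabilities must sum to 1")
        if self.kind == "at_rich_motif" and dr_length is not None:
            if len(self.motif) != dr_length:
                raise ValueError("motif length must equal the DR length it induces")


def _corrupt(seq: str, p: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < p:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _sample_sites_uniform(rng, genome_length, n, min_gap, max_tries=20000):
    sites: list[int] = []
    tries = 0
    while len(sites) < n and tries < max_tries:
        tries += 1
        p = int(rng.integers(min_gap, genome_length - min_gap))
        if all(abs(p - q) >= min_gap for q in sites):
            sites.append(p)
    if len(sites) < n:
        raise ValueError("genome too short for the requested non-overlapping insertions")
    return sites


def _write_promoter(arr: list[str], junction: int, direction: int,
                    offset: int, spacer: int, model: SiteModel,
                    rng: np.random.Generator) -> None:
    """Write corrupted -35/-10 boxes into the genome reading away from the
    junction (``direction`` +1 rightward, -1 leftward on the bottom strand)."""
    b35 = _corrupt(model.box35, model.corruption, rng)
    b10 = _corrupt(model.box10, model.corruption, rng)
    if direction > 0:
        s35 = junction + offset
        s10 = s35 + 6 + spacer
        arr[s35:s35 + 6] = list(b35)
        arr[s10:s10 + 6] = list(b10)
    else:
        e35 = junction - offset
        arr[e35 - 6:e35] = list(revcomp(b35))
        e10 = e35 - 6 - spacer
        arr[e10 - 6:e10] = list(revcomp(b10))


def plant_insertions(
    genome_length: int,
    tes: Sequence[PlantedTE],
    site_model: SiteModel,
    n_insertions: int,
    seed: int,
    *,
    genome_id: str = "synth_genome",
    gc: float = 0.40,
    min_gap: int = 900,
    max_genome_resamples: int = 20,
) -> tuple[SeqRecord, pd.DataFrame]:
    """Plant ``n_insertions`` copies of the given elements into a random
    genome, duplicating the target site so every element is flanked by
    identical DRs.

    Elements are recycled in order when ``n_insertions > len(tes)`` (that is
    how multi-copy evidence for boundary calling arises).  Strand is sampled
    uniformly.  Truth coordinates (0-based half-open, on the emitted genome)
    are returned as a DataFrame with one row per insertion.
    """
    site_model.validate(dr_length=tes[0].dr_length if tes else None)
    if not tes:
        raise ValueError("no elements to plant")
    rng = np.random.default_rng(seed)

    for attempt in range(max_genome_resamples):
        genome0 = random_nt(rng, genome_length, gc=gc)
        if site_model.kind == "at_rich_motif":
            pat = iupac_regex(site_model.motif)
            candidates = [m.start() for m in pat.finditer(genome0)
                          if min_gap <= m.start() <= genome_length - min_gap]
            rng.shuffle(candidates)
            sites: list[int] = []
            for p in candidates:
                if all(abs(p - q) >= min_gap for q in sites):
                    sites.append(p)
                if len(sites) == n_insertions:
                    break
            if len(sites) < n_insertions:
                logger.warning(
                    "motif %s found at only %d usable sites; resampling background",
                    site_model.motif, len(sites))
                continue
        else:
            sites = _sample_sites_uniform(rng, genome_length, n_insertions, min_gap)
        break
    else:
        raise ValueError("could not place all insertions after resampling background")

    plan = []
    for i, p in enumerate(sorted(sites)):
        te = tes[i % len(tes)]
        strand = "+" if rng.random() < 0.5 else "-"
        plan.append((p, te, strand))

    # assemble the emitted genome left to right, duplicating the target site
    pieces: list[str] = []
    rows = []
    prev = 0
    shift = 0
    for copy_idx, (p, te, strand) in enumerate(plan):
        dr = genome0[p:p + te.dr_length]
        if site_model.kind == "at_rich_motif" and not matches_iupac(dr, site_model.motif):
            raise AssertionError("target site does not match motif")  # defensive
        elem = te.sequence if strand == "+" else revcomp(te.sequence)
        pieces.append(genome0[prev:p + te.dr_length])
        pieces.append(elem)
        prev = p
        start = p + te.dr_length + shift
        end = start + len(elem)
        shift += len(elem) + te.dr_length
        if strand == "+":
            cds = (start + te.cds_start, start + te.cds_end)
        else:
            cds = (end - te.cds_end, end - te.cds_start)
        rows.append({
            "te_id": f"{te.te_id}.{copy_idx}", "element_id": te.te_id,
            "genome_id": genome_id, "start": start, "end": end,
            "strand": strand, "dr_sequence": dr,
            "cds_start": cds[0], "cds_end": cds[1],
            "promoter_offset": None, "promoter_side": None,
            "family_id": te.family_id,
        })
    pieces.append(genome0[prev:])
    arr = list("".join(pieces))

    # write promoters after assembly so coordinates are final
    if site_model.kind == "promoter_offset":
        offsets = sorted(site_model.offset_distribution)
        probs = [site_model.offset_distribution[o] for o in offsets]
        for row in rows:
            d = int(rng.choice(offsets, p=probs))
            sp = int(rng.integers(site_model.spacer_range[0],
                                  site_model.spacer_range[1] + 1))
            if site_model.orientation_rule == "irr_toward_promoter":
                side = "IRr"
            else:
                side = "IRr" if rng.random() < 0.5 else "IRl"
            # junction coordinate and reading direction of the chosen side
            if (side == "IRr") == (row["strand"] == "+"):
                junction, direction = row["end"], +1
            else:
                junction, direction = row["start"], -1
            _write_promoter(arr, junction, direction, d, sp, site_model, rng)
            row["promoter_offset"] = d
            row["promoter_side"] = side

    genome = SeqRecord(Seq("".join(arr)), id=genome_id, description="")
    truth = pd.DataFrame(rows)
    return genome, truth


def emit_circular_junction(
    te: PlantedTE,
    linker_length: int,
    flank_source: str = "left",
    seed: int = 0,
    flanks: tuple[str, str] | None = None,
) -> SeqRecord:
    """The IRr-linker-IRl junction of a circular transposition intermediate.

    The two terminal IRs are abutted, separated by a 6-10 bp linker copied
    from one of the element's flanking sequences at its prior insertion site
    (random context when none is given).
    """
    if not 6 <= linker_length <= 10:
        raise ValueError("linker length must lie in [6, 10]")
    if flank_source not in {"left", "right"}:
        raise ValueError("flank_source must be 'left' or 'right'")
    if flanks is None:
        rng = np.random.default_rng(seed)
        flanks = (random_nt(rng, 50), random_nt(rng, 50))
    flank = flanks[0] if flank_source == "left" else flanks[1]
    if len(flank) < linker_length:
        raise ValueError("flank shorter than requested linker")
    linker = flank[:linker_length]
    seq = te.ir_right + linker + te.ir_left
    return SeqRecord(Seq(seq), id=f"{te.te_id}_circle_junction", description="")


# ---------------------------------------------------------------------------
# Truth/record output
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[SeqRecord], path) -> None:
    from Bio import SeqIO
    SeqIO.write(list(records), str(path), "fasta")


def write_truth_gff3(truth: pd.DataFrame, path) -> None:
    """Truth table as GFF3 (1-based inclusive, attributes in column 9)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in truth.iterrows():
            attrs = [f"ID={r.te_id}", f"family={r.family_id}",
                     f"dr_sequence={r.dr_sequence}"]
            if r.promoter_offset is not None and not pd.isna(r.promoter_offset):
                attrs.append(f"promoter_offset={int(r.promoter_offset)}")
                attrs.append(f"promoter_side={r.promoter_side}")
            fh.write("\t".join([
                str(r.genome_id), "mulescan_synth", "mobile_genetic_element",
                str(int(r.start) + 1), str(int(r.end)), ".", str(r.strand), ".",
                ";".join(attrs)]) + "\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
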