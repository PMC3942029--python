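"""Canonical synthetic scenarios ("fixture profiles").

Each profile pins one study condition exercised by the pipeline, with
defaults chosen once to reflect the biology being emulated:

* ``families5`` -- five transposase families (8 members each) descended from
  one shared root.  Root divergence 0.75 substitutions/site keeps
  between-family identity near the twilight zone (~15-20%, connected only
  through the invariant anchor blocks, so the similarity graph is
  interlinked) while member divergence 0.22 keeps within-family identity
  above 60%.
* ``promoter_bias`` -- 500 insertions of four p-MULT 3-style elements whose
  IRr-genome junction sits 15-17 bp (mode 16) upstream of a planted sigma-A
  promoter, IRr always facing the promoter.
* ``ish6_motif`` -- 50 insertions of five IS*H6*-style elements targeting
  the AT-rich 8-mer ``AANATNTT``, which becomes the duplicated target site.
* ``uniform_te`` -- unbiased multi-copy insertions (boundary/DR/IR recovery
  conditions; also the null for promoter enrichment).
* ``frameshift`` -- an element whose transposase is split across two ORFs
  rejoined by a -1 ribosomal frameshift.
* ``chain_homology`` -- three families A-B-C where only the middle family is
  detectably similar to both ends (anchor blocks shortened so the A-C link
  is below matrix-search sensitivity); the regime where iterative
  re-querying through distant hits outperforms a single search.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import simulate
from .simulate import FamilySpec, PlantedTE, SiteModel, make_planted_te

PROFILES = ("families5", "promoter_bias", "ish6_motif", "uniform_te",
            "frameshift", "chain_homology")


# ---------------------------------------------------------------------------
# Protein-family profiles
# ---------------------------------------------------------------------------

def families5_specs(n_members: int = 8) -> list[FamilySpec]:
    return [
        FamilySpec(family_id=f"pMULT{i}", n_members=n_members,
                   substitution_rate=0.22, root_divergence=0.75)
        for i in range(1, 6)
    ]


def make_families5(seed: int, n_members: int = 8):
    return simulate.generate_protein_families(families5_specs(n_members), seed)


def chain_specs(n_members: int = 6) -> list[FamilySpec]:
    """A three-family transitive-homology chain A <-> B <-> C.

    The middle family's ancestor *is* the root; the two end families
    diverge from it in opposite directions, so each end is detectably
    similar to the middle but the ends are mutually near the twilight zone.
    """
    common = dict(n_members=n_members, substitution_rate=0.15)
    return [
        FamilySpec(family_id="famA", root_divergence=0.65, **common),
        FamilySpec(family_id="famB", root_divergence=0.0, **common),
        FamilySpec(family_id="famC", root_divergence=0.65, **common),
    ]


def make_chain(seed: int, n_members: int = 6):
    return simulate.generate_protein_families(chain_specs(n_members), seed)


#: ungapped segment (reference coordinates) of the promoter-targeting
#: signature planted between the N1 and N2 anchor blocks
SIGNATURE_BLOCK = (19, 27)


def signature_specs(n_members: int = 10) -> list[FamilySpec]:
    """Three groups for differential-conservation analysis.

    The reference group A is a coherent family; the two partner groups are
    internally diverse (members drawn independently from the common root at
    0.55 substitutions/site, the way a deep IS group looks).  A and B1 (the
    promoter-targeting pair) share an invariant block between the N1 and N2
    anchors, which diverges freely in B2.
    """
    sig = (SIGNATURE_BLOCK,)
    return [
        FamilySpec(family_id="groupA", n_members=n_members,
                   substitution_rate=0.15, root_divergence=0.0,
                   extra_conserved_blocks=sig),
        FamilySpec(family_id="groupB1", n_members=n_members,
                   substitution_rate=0.55, root_divergence=0.0,
                   extra_conserved_blocks=sig),
        FamilySpec(family_id="groupB2", n_members=n_members,
                   substitution_rate=0.55, root_divergence=0.0),
    ]


def make_signature_alignments(seed: int, n_members: int = 10):
    """(alignment A+B1, alignment A+B2, truth) -- members are generated
    without indels, so rows stack into ungapped alignments directly."""
    from .conservation import AlignmentBlock
    records, truth = simulate.generate_protein_families(
        signature_specs(n_members), seed)
    seqs = {r.id: str(r.seq) for r in records}
    group = {mid: fid for mid, fid in truth.members.items()}
    ids_a = sorted(m for m in group if group[m] == "groupA")
    ids_b1 = sorted(m for m in group if group[m] == "groupB1")
    ids_b2 = sorted(m for m in group if group[m] == "groupB2")
    ab1 = AlignmentBlock(ids=ids_a + ids_b1, rows=[seqs[i] for i in ids_a + ids_b1])
    ab2 = AlignmentBlock(ids=ids_a + ids_b2, rows=[seqs[i] for i in ids_a + ids_b2])
    return ab1, ab2, truth


# ---------------------------------------------------------------------------
# Genome / insertion profiles
# ---------------------------------------------------------------------------

def promoter_site_model() -> SiteModel:
    """The p-MULT 3 geometry: -35 box 15-17 bp (mode 16) from the IRr
    junction, IRr toward the promoter."""
    return SiteModel(kind="promoter_offset",
                     offset_distribution={15: 0.25, 16: 0.5, 17: 0.25},
                     orientation_rule="irr_toward_promoter")


def ish6_site_model() -> SiteModel:
    return SiteModel(kind="at_rich_motif", motif="AANATNTT")


def _small_tes(rng: np.random.Generator, n: int, dr_length: int,
               prefix: str, cds_aa_length: int = 300) -> list[PlantedTE]:
    return [make_planted_te(f"{prefix}{i}", rng, dr_length=dr_length,
                            cds_aa_length=cds_aa_length,
                            ir_length=int(rng.integers(18, 40)))
            for i in range(1, n + 1)]


def make_promoter_bias(seed: int, n_insertions: int = 500,
                       genome_length: int = 1_500_000):
    """Genome with promoter-targeted insertions (four elements recycled)."""
    rng = np.random.default_rng(seed)
    tes = _small_tes(rng, 4, dr_length=9, prefix="tnGBS")
    genome, truth = simulate.plant_insertions(
        genome_length, tes, promoter_site_model(), n_insertions, seed + 1)
    return genome, truth, tes


def make_ish6(seed: int, n_insertions: int = 50,
              genome_length: int = 200_000, n_elements: int = 5):
    """200 kb genome with AT-rich-motif-targeted insertions, multi-copy."""
    rng = np.random.default_rng(seed)
    tes = _small_tes(rng, n_elements, dr_length=8, prefix="ISH6_")
    genome, truth = simulate.plant_insertions(
        genome_length, tes, ish6_site_model(), n_insertions, seed + 1)
    return genome, truth, tes


def make_uniform(seed: int, n_insertions: int = 30,
                 genome_length: int = 200_000, n_elements: int = 6):
    """Uniform-random multi-copy insertions (>=5 copies per element)."""
    rng = np.random.default_rng(seed)
    tes = _small_tes(rng, n_elements, dr_length=9, prefix="IS256_")
    genome, truth = simulate.plant_insertions(
        genome_length, tes, SiteModel(kind="uniform"), n_insertions, seed + 1)
    return genome, truth, tes


def make_frameshift(seed: int, n_insertions: int = 5,
                    genome_length: int = 80_000):
    """One frameshift-split element planted in multiple copies."""
    rng = np.random.default_rng(seed)
    te = make_planted_te("ISMich2", rng, dr_length=9, cds_aa_length=350,
                         frameshift_split=True)
    genome, truth = simulate.plant_insertions(
        genome_length, [te], SiteModel(kind="uniform"), n_insertions, seed + 1)
    return genome, truth, te


# ---------------------------------------------------------------------------
# Packaging for the CLI
# ---------------------------------------------------------------------------

def write_fixture(profile: str, outdir, seed: int) -> list[str]:
    """Write the named scenario (FASTA + truth tables) into *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save_genome(genome, truth):
        fa = out / f"{profile}.genome.fasta"
        simulate.write_fasta([genome], fa)
        gff = out / f"{profile}.truth.gff3"
        simulate.write_truth_gff3(truth, gff)
        tsv = out / f"{profile}.truth.tsv"
        simulate.write_truth_tsv(truth, tsv)
        written.extend([str(fa), str(gff), str(tsv)])

    if profile in ("families5", "chain_homology"):
        records, truth = (make_families5(seed) if profile == "families5"
                          else make_chain(seed))
        fa = out / f"{profile}.proteins.fasta"
        simulate.write_fasta(records, fa)
        tsv = out / f"{profile}.truth.tsv"
        truth.to_frame().to_csv(tsv, sep="\t", index=False)
        written.extend([str(fa), str(tsv)])
    elif profile == "promoter_bias":
        genome, truth, _ = make_promoter_bias(seed)
        _save_genome(genome, truth)
    elif profile == "ish6_motif":
        genome, truth, _ = make_ish6(seed)
        _save_genome(genome, truth)
    elif profile == "uniform_te":
        genome, truth, _ = make_uniform(seed)
        _save_genome(genome, truth)
    elif profile == "frameshift":
        genome, truth, _ = make_frameshift(seed)
        _save_genome(genome, truth)
    else:
        raise ValueError(
            f"unknown profile {profile!r}; available: {', '.join(PROFILES)}")
    return written
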