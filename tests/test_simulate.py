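"""Synthetic-data generator: truth fidelity, conserved-motif exemption,
insertion bookkeeping and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mulescan import fixtures, simulate
from mulescan.seqs import matches_iupac, revcomp
from mulescan.simulate import FamilySpec, SiteModel, make_planted_te


def ident(a, b):
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestProteinFamilies:
    def test_zero_rate_members_equal_ancestor(self):
        spec = FamilySpec(family_id="f", n_members=1, substitution_rate=0.0)
        records, truth = simulate.generate_protein_families([spec], seed=0)
        assert str(records[0].seq) == truth.ancestors["f"]

    def test_within_family_identity_exceeds_between(self):
        specs = [FamilySpec(family_id=f, n_members=4, substitution_rate=0.3)
                 for f in ("fa", "fb")]
        records, truth = simulate.generate_protein_families(specs, seed=3)
        seqs = {r.id: str(r.seq) for r in records}
        within, between = [], []
        ids = sorted(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                bucket = within if truth.members[a] == truth.members[b] else between
                bucket.append(ident(seqs[a], seqs[b]))
        assert np.mean(within) > np.mean(between)

    def test_catalytic_residues_exempt_from_substitution(self):
        spec = FamilySpec(family_id="f", n_members=10, substitution_rate=0.4)
        records, _ = simulate.generate_protein_families([spec], seed=1)
        d1, d2, e = spec.triad_positions
        for r in records:
            s = str(r.seq)
            assert (s[d1], s[d2], s[e]) == ("D", "D", "E")
            assert s[d2 + spec.cdh_offset] in "CD"
            assert s[d2 + spec.cdh_offset + 3] == "H"

    def test_anchor_blocks_invariant_within_family(self):
        spec = FamilySpec(family_id="f", n_members=6, substitution_rate=0.5)
        records, truth = simulate.generate_protein_families([spec], seed=2)
        anc = truth.ancestors["f"]
        for s, t in spec.anchor_blocks:
            assert all(str(r.seq)[s:t] == anc[s:t] for r in records)

    @pytest.mark.parametrize("bad", [
        dict(triad_positions=(170, 100, 280)),       # not increasing
        dict(cdh_offset=10),                          # below signature range
        dict(cdh_offset=20),                          # above signature range
        dict(triad_positions=(100, 200, 280)),        # insert below 99 aa
        dict(anchor_blocks=((10, 20), (15, 30))),     # overlapping blocks
        dict(n_members=0),
        dict(substitution_rate=1.0),
    ])
    def test_invalid_specs_rejected(self, bad):
        params = {"family_id": "f", "n_members": 2, **bad}
        spec = FamilySpec(**params)
        with pytest.raises(ValueError):
            spec.validate()

    def test_determinism_identical_seeds(self):
        a, _ = fixtures.make_families5(9, n_members=3)
        b, _ = fixtures.make_families5(9, n_members=3)
        assert [(r.id, str(r.seq)) for r in a] == [(r.id, str(r.seq)) for r in b]


class TestPlantedElements:
    def test_element_reads_g_to_c_and_irs_complementary(self, rng):
        te = make_planted_te("t", rng, ir_length=30, complementarity=0.9)
        assert te.sequence.startswith("G") and te.sequence.endswith("C")
        rc = revcomp(te.ir_left)
        assert ident(rc, te.ir_right) >= 0.83

    def test_length_accounting_single_uniform_insertion(self, rng):
        te = make_planted_te("t", rng, dr_length=9)
        genome, truth = simulate.plant_insertions(
            60_000, [te], SiteModel(kind="uniform"), 1, seed=4)
        assert len(genome.seq) == 60_000 + len(te.sequence) + 9

    def test_point_mass_offset_recorded_in_every_truth_row(self, rng):
        te = make_planted_te("t", rng)
        model = SiteModel(kind="promoter_offset", offset_distribution={16: 1.0})
        _, truth = simulate.plant_insertions(120_000, [te], model, 6, seed=4)
        assert list(truth.promoter_offset) == [16] * 6

    def test_at_rich_model_duplicates_motif_site(self, rng):
        te = make_planted_te("t", rng, dr_length=8)
        genome, truth = simulate.plant_insertions(
            120_000, [te], SiteModel(kind="at_rich_motif"), 8, seed=4)
        g = str(genome.seq)
        for row in truth.itertuples():
            assert len(row.dr_sequence) == 8
            assert matches_iupac(row.dr_sequence, "AANATNTT")
            assert g[row.end:row.end + 8] == row.dr_sequence

    def test_motif_length_must_match_dr_length(self, rng):
        te = make_planted_te("t", rng, dr_length=9)
        with pytest.raises(ValueError, match="motif length"):
            simulate.plant_insertions(
                120_000, [te], SiteModel(kind="at_rich_motif"), 2, seed=0)

    def test_truth_reextraction_and_dr_fidelity(self, uniform_te):
        genome, truth, tes = uniform_te
        by_id = {t.te_id: t for t in tes}
        for row in truth.itertuples():
            planted = by_id[row.element_id].sequence
            if row.strand == "-":
                planted = revcomp(planted)
            assert genome[row.start:row.end] == planted
            L = len(row.dr_sequence)
            assert genome[row.start - L:row.start] == row.dr_sequence
            assert genome[row.end:row.end + L] == row.dr_sequence

    def test_genome_determinism(self):
        g1, t1, _ = fixtures.make_uniform(8, n_insertions=5, genome_length=40_000)
        g2, t2, _ = fixtures.make_uniform(8, n_insertions=5, genome_length=40_000)
        assert str(g1.seq) == str(g2.seq)
        assert t1.equals(t2)

    def test_genome_too_short_raises(self, rng):
        te = make_planted_te("t", rng)
        with pytest.raises(ValueError, match="too short"):
            simulate.plant_insertions(5_000, [te], SiteModel(kind="uniform"),
                                      10, seed=0)


class TestCircularJunction:
    def test_junction_length_and_linker_copy(self, rng):
        te = make_planted_te("t", rng, ir_length=24)
        flanks = ("ACGTACGTACGTACG", "TTTTGGGGCCCCAAA")
        rec = simulate.emit_circular_junction(te, 10, "left", flanks=flanks)
        seq = str(rec.seq)
        assert len(seq) == 24 + 10 + 24
        assert seq[24:34] == flanks[0][:10]
        assert seq.startswith(te.ir_right) and seq.endswith(te.ir_left)

    @pytest.mark.parametrize("linker", [5, 11])
    def test_linker_length_bounds_enforced(self, rng, linker):
        te = make_planted_te("t", rng)
        with pytest.raises(ValueError):
            simulate.emit_circular_junction(te, linker, "left")

    def test_junction_detectable_by_ir_finder(self, rng):
        from mulescan import boundaries
        te = make_planted_te("t", rng, ir_length=24)
        rec = str(simulate.emit_circular_junction(te, 8, "left", seed=1).seq)
        ir = boundaries.find_inverted_repeats(rec, require_terminal_c=False)
        assert ir is not None
        # the called pair must cover the abutted terminal repeats
        assert ir.left[0] <= 1 and ir.right[1] >= len(rec) - 1
        assert ir.left[1] - ir.left[0] >= 22


class TestFrameshiftConstruction:
    def test_minus1_slip_restores_full_protein(self, rng):
        from Bio.Seq import Seq
        te = make_planted_te("t", rng, cds_aa_length=200, frameshift_split=True)
        (a, b), (c, d) = te.orfs
        assert c < b, "ORFs must overlap"
        s = te.fs_junction
        chimera = te.sequence[a:s] + te.sequence[s - 1:d]
        prot = str(Seq(chimera).translate())
        assert "*" not in prot[:-1]
        assert len(prot) >= 200


@given(st.text(alphabet="ACGT", min_size=1, max_size=80))
@settings(deadline=None, max_examples=50)
def test_revcomp_is_an_involution(s):
    assert revcomp(revcomp(s)) == s


@given(st.integers(0, 2 ** 31 - 1))
@settings(deadline=None, max_examples=20)
def test_random_nt_deterministic_per_seed(seed):
    a = simulate.random_nt(np.random.default_rng(seed), 50)
    b = simulate.random_nt(np.random.default_rng(seed), 50)
    assert a == b
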