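"""Boundary calling, IR/DR validation and frameshift detection."""

import numpy as np
import pytest

from mulescan import boundaries, fixtures
from mulescan.boundaries import (DirectRepeat, GenomicHit,
                                 InsufficientCopiesError, detect_dr,
                                 detect_minus1_frameshift, extract_with_flanks,
                                 find_inverted_repeats, ir_complementarity,
                                 majority_boundaries, seed_extend_hits)
from mulescan.seqs import random_nt, revcomp


def gh(qs, qe, ss=None, se=None):
    ss = qs if ss is None else ss
    se = qe if se is None else se
    return GenomicHit("q", "g", qs, qe, ss, se, "+", 100.0)


class TestExtractWithFlanks:
    def test_flank_arithmetic(self):
        rec = extract_with_flanks("A" * 10_000, 1000, 2000, flank=400)
        assert len(rec.sequence) == 1000 + 2 * 400 and rec.offset == 600

    def test_contig_start_truncates_with_flag(self):
        rec = extract_with_flanks("A" * 10_000, 50, 500, flank=400)
        assert rec.truncated_left and not rec.truncated_right
        assert rec.offset == 0 and len(rec.sequence) == 900

    def test_back_mapping_round_trip(self):
        rec = extract_with_flanks("A" * 5_000, 700, 900, flank=100)
        assert rec.to_genome(0) == 600
        assert rec.to_genome(150) == 750

    def test_cds_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            extract_with_flanks("A" * 100, 50, 200)


class TestMajorityBoundaries:
    def test_modal_start_and_end(self):
        hits = [gh(12, 2400), gh(12, 2400), gh(12, 2400), gh(300, 900)]
        assert majority_boundaries(hits) == (12, 2400)

    def test_bimodal_tie_takes_maximal_element(self):
        hits = [gh(10, 100), gh(10, 200), gh(20, 100), gh(20, 200)]
        assert majority_boundaries(hits) == (10, 200)

    def test_too_few_copies_signal_related_isolate_path(self):
        with pytest.raises(InsufficientCopiesError):
            majority_boundaries([gh(0, 10), gh(0, 10)])

    def test_no_hits_is_an_error(self):
        with pytest.raises(ValueError):
            majority_boundaries([])


class TestSeedExtend:
    def test_planted_copy_found_on_both_strands(self, rng):
        insert = random_nt(rng, 300)
        genome = random_nt(rng, 5_000) + insert + random_nt(rng, 3_000) \
            + revcomp(insert) + random_nt(rng, 2_000)
        hits = seed_extend_hits(insert, genome, min_score=100)
        spans = {(h.s_start, h.s_end, h.strand) for h in hits}
        assert (5_000, 5_300, "+") in spans
        assert (8_300, 8_600, "-") in spans
        fwd = [h for h in hits if h.strand == "+" and h.s_start == 5_000][0]
        assert (fwd.q_start, fwd.q_end) == (0, 300)
        assert fwd.identity == 100.0


class TestInvertedRepeats:
    def make_record(self, rng, ir_len=24, mismatches=0, terminal="GC"):
        # G appears only at the left IR terminus (so C only at the right
        # one), making the terminal-base rule decisive for every candidate
        tail = "".join(rng.choice(list("ACT"), size=ir_len - 1))
        ir_left = terminal[0] + tail
        ir_right = list(revcomp(ir_left))
        for p in range(1, mismatches + 1):
            ir_right[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ir_right[p]]
        ir_right[-1] = terminal[1]
        return ir_left + random_nt(rng, 400) + "".join(ir_right)

    def test_perfect_planted_ir_found_exactly(self, rng):
        rec = self.make_record(rng, ir_len=24)
        ir = find_inverted_repeats(rec)
        assert ir.left == (0, 24, rec[:24])
        assert ir.right == (len(rec) - 24, len(rec), rec[-24:])
        assert ir.mismatches == 0

    def test_terminal_base_rule_filters_wrong_terminus(self, rng):
        rec = self.make_record(rng, terminal="GG")  # right terminus not C
        assert find_inverted_repeats(rec, require_terminal_c=True) is None
        assert find_inverted_repeats(rec, require_terminal_c=False) is not None

    def test_repeat_below_minimum_length_ignored(self, rng):
        # at exact stringency a 17 bp repeat cannot support an 18+ bp call
        rec = self.make_record(rng, ir_len=17)
        assert find_inverted_repeats(rec, max_mismatch_frac=0.0) is None

    def test_strand_symmetry(self, rng):
        rec = self.make_record(rng, ir_len=30, mismatches=2)
        ir = find_inverted_repeats(rec)
        mirrored = find_inverted_repeats(revcomp(rec))
        n = len(rec)
        assert mirrored.left == (n - ir.right[1], n - ir.right[0],
                                 revcomp(ir.right[2]))
        assert mirrored.right == (n - ir.left[1], n - ir.left[0],
                                  revcomp(ir.left[2]))
        assert mirrored.mismatches == ir.mismatches


class TestDirectRepeats:
    def test_planted_9bp_duplication_recovered(self, rng):
        dr = random_nt(rng, 9)
        genome = random_nt(rng, 500) + dr + random_nt(rng, 1000) + dr + random_nt(rng, 500)
        start, end = 509, 1509
        found = detect_dr(genome, start, end)
        assert found == DirectRepeat(9, dr, dr)

    def test_absent_duplication_returns_none(self, rng):
        genome = random_nt(rng, 3000)
        assert detect_dr(genome, 1000, 2000) is None

    def test_longest_matching_length_wins(self):
        # a homopolymeric target site matches at both 8 and 9 bp: report 9
        dr = "A" * 9
        genome = "T" * 100 + dr + "G" * 50 + dr + "T" * 100
        found = detect_dr(genome, 109, 159)
        assert found.length == 9


class TestIRComplementarity:
    def test_exact_reverse_complement_scores_100(self, rng):
        ir = random_nt(rng, 24)
        assert ir_complementarity(ir, revcomp(ir)) == pytest.approx(100.0)

    def test_one_mismatch_in_24(self, rng):
        ir = random_nt(rng, 24)
        other = list(revcomp(ir))
        other[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[10]]
        assert ir_complementarity(ir, "".join(other)) == pytest.approx(95.8, abs=0.05)

    def test_unrelated_sequences_score_low(self):
        vals = []
        for s in range(20):
            r = np.random.default_rng(100 + s)
            vals.append(ir_complementarity(random_nt(r, 20), random_nt(r, 20)))
        assert np.mean(vals) < 60.0


class TestFrameshift:
    def test_planted_split_element_detected_at_slip_site(self, rng):
        from mulescan.simulate import make_planted_te
        te = make_planted_te("t", rng, cds_aa_length=250, frameshift_split=True)
        found, junction = detect_minus1_frameshift(te.sequence, list(te.orfs))
        assert found and junction == te.fs_junction

    def test_same_frame_orfs_separated_by_stop_not_called(self):
        seq = "ATG" + "GCA" * 50 + "TAA" + "ATG" + "GCA" * 50 + "TAA"
        orfs = [(0, 156), (156, 312)]
        assert detect_minus1_frameshift(seq, orfs) == (False, None)

    def test_single_orf_not_called(self):
        seq = "ATG" + "GCA" * 100 + "TAA"
        assert detect_minus1_frameshift(seq, [(0, len(seq))]) == (False, None)


class TestAnnotationPipeline:
    def test_multicopy_elements_recover_truth(self, uniform_te):
        genome, truth, _ = uniform_te
        sample = truth.head(8)
        for row in sample.itertuples():
            ann = boundaries.annotate_element(
                genome, row.cds_start, row.cds_end, te_id=row.te_id)
            assert abs(ann.start - row.start) <= 2
            assert abs(ann.end - row.end) <= 2
            assert ann.dr is not None
            assert ann.dr.left_seq == row.dr_sequence
            assert ann.ir is not None
            assert 18 <= ann.ir.left[1] - ann.ir.left[0] <= 39
            assert ann.copy_count > 3
            assert not ann.frameshift

    def test_frameshift_element_flagged_by_pipeline(self):
        genome, truth, te = fixtures.make_frameshift(4)
        g = str(genome.seq)
        row = truth.iloc[0]
        ann = boundaries.annotate_element(g, int(row.cds_start),
                                          int(row.cds_end), te_id=row.te_id)
        assert ann.frameshift
        assert (ann.start, ann.end) == (row.start, row.end)
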