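"""Conservation profiling: gap filtering, windowed similarity curves, triad
anchoring and differential signatures."""

import numpy as np
import pytest

from mulescan import conservation, fixtures
from mulescan._align import AA, AA_INDEX, blosum62_20x20
from mulescan.conservation import (AlignmentBlock, anchor_triad,
                                   differential_conservation,
                                   filter_gap_columns, locate_anchor_domains,
                                   scan_cdh_motif, windowed_conservation)


def random_alignment(rng, n=5, length=60, gap_p=0.10):
    alphabet = list(AA) + ["-"]
    p = [(1 - gap_p) / 20] * 20 + [gap_p]
    return [("".join(rng.choice(alphabet, size=length, p=p))) for _ in range(n)]


def brute_force_profile(rows, window, gap_score=-4.0):
    """Independent recomputation: explicit all-pairs loops."""
    mat = blosum62_20x20()
    L, n = len(rows[0]), len(rows)
    cols = []
    for j in range(L):
        tot, cnt = 0.0, 0
        for a in range(n):
            for b in range(a + 1, n):
                x, y = rows[a][j], rows[b][j]
                if x == "-" and y == "-":
                    continue
                tot += gap_score if "-" in (x, y) else mat[AA_INDEX[x], AA_INDEX[y]]
                cnt += 1
        cols.append(tot / cnt if cnt else 0.0)
    half = window // 2
    return np.array([np.mean(cols[max(0, j - half):min(L, j + window - half)])
                     for j in range(L)])


class TestGapFilter:
    def test_gap_free_alignment_unchanged(self):
        block = AlignmentBlock(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert filter_gap_columns(block).rows == ["ACDE", "ACDE"]

    def test_column_above_threshold_removed(self):
        rows = ["A-CD", "A-CD", "A-CD", "AACD"]  # col 1: 3/4 gaps
        block = filter_gap_columns(AlignmentBlock(ids=list("wxyz"), rows=rows))
        assert block.rows == ["ACD", "ACD", "ACD", "ACD"]

    def test_exactly_at_threshold_kept(self):
        rows = ["A-C", "A-C", "A-C", "AAC", "AAC"]  # col 1: 3/5 = 0.6 gaps
        block = filter_gap_columns(AlignmentBlock(ids=list("vwxyz"), rows=rows))
        assert block.n_columns == 3

    def test_all_columns_removed_is_an_error(self):
        block = AlignmentBlock(ids=["a", "b"], rows=["--", "A-"])
        with pytest.raises(ValueError):
            filter_gap_columns(block, max_gap_frac=0.4)


class TestWindowedConservation:
    def test_identical_tryptophan_rows_score_matrix_diagonal(self):
        prof = windowed_conservation(["WWW", "WWW"], window=15)
        assert np.allclose(prof, 11.0)  # BLOSUM62 W-W

    def test_constant_minus4_profile_for_d_vs_l_rows(self):
        prof = windowed_conservation(["DDDDD", "LLLLL"], window=3)
        assert np.allclose(prof, -4.0)  # BLOSUM62 D-L

    def test_window_one_equals_raw_column_scores(self, rng):
        rows = random_alignment(rng)
        assert np.allclose(windowed_conservation(rows, window=1),
                           conservation.column_scores(rows))

    def test_matches_brute_force_recomputation(self, rng):
        for _ in range(3):
            rows = random_alignment(rng)
            assert np.allclose(windowed_conservation(rows, window=15),
                               brute_force_profile(rows, 15), atol=1e-12)

    def test_row_order_invariance(self, rng):
        rows = random_alignment(rng)
        shuffled = rows[::-1]
        assert np.allclose(windowed_conservation(rows, window=15),
                           windowed_conservation(shuffled, window=15))


class TestTriadAnchoring:
    def test_reference_aligned_to_itself_returns_reference_triad(self):
        seq = "M" * 10 + "D" + "A" * 9 + "D" + "A" * 13 + "CAAH" + "K" * 82 + "E" + "A" * 10
        block = AlignmentBlock(ids=["ref", "copy"], rows=[seq, seq])
        calls = anchor_triad(block, "ref", (10, 20, 120))
        for c in calls:
            assert (c.d1, c.d2, c.e) == (10, 20, 120)
            assert c.insert_length == 100
            assert c.cdh_offset == 14

    def test_gap_at_d2_column_flagged_without_cdh_scan(self):
        ref = "AADAADAAE"
        gapped = "AADAA-AAE"
        # reference triad: D at 2, D at 5, E at 8 (toy indices)
        block = AlignmentBlock(ids=["ref", "g"], rows=[ref, gapped])
        calls = anchor_triad(block, "ref", (2, 5, 8), cdh_range=(1, 2))
        g = calls[1]
        assert g.d2 is None
        assert "d2_gapped" in g.flags
        assert g.cdh_offset is None

    def test_synthetic_family_rows_match_spec_truth(self, families5):
        seqs, truth = families5
        fam = "pMULT2"
        ids = sorted(m for m, f in truth.members.items() if f == fam)
        block = AlignmentBlock(ids=ids, rows=[seqs[i] for i in ids])
        spec = truth.specs[fam]
        calls = anchor_triad(block, ids[0], spec.triad_positions)
        assert all(c.complete for c in calls)
        assert all((c.d1, c.d2, c.e) == spec.triad_positions for c in calls)
        assert all(c.cdh_offset == spec.cdh_offset for c in calls)
        assert all(99 <= c.insert_length <= 138 for c in calls)


class TestCDHScan:
    SEQ = "A" * 50 + "D" + "A" * 13 + "CXXH".replace("X", "A") + "A" * 50

    def test_planted_signature_at_14(self):
        assert scan_cdh_motif(self.SEQ, 50) == 14

    def test_aspartate_variant_accepted(self):
        seq = "A" * 50 + "D" + "A" * 10 + "DAAH" + "A" * 50
        assert scan_cdh_motif(seq, 50) == 11

    def test_signature_outside_range_ignored(self):
        seq = "A" * 50 + "D" + "A" * 24 + "CAAH" + "A" * 50
        assert scan_cdh_motif(seq, 50) is None


class TestAnchorDomains:
    def test_three_planted_plateaus_located(self):
        prof = np.zeros(300)
        for s, e in ((20, 40), (80, 100), (200, 230)):
            prof[s:e] = 5.0
        regions = locate_anchor_domains(prof, n_domains=3, threshold=2.0)
        assert [(r.start, r.end) for r in regions] == [(20, 40), (80, 100), (200, 230)]

    def test_flat_profile_has_no_regions(self):
        regions = locate_anchor_domains(np.ones(100), threshold=2.0)
        assert regions == []

    def test_greedy_best_first_enforces_non_overlap(self):
        prof = np.zeros(100)
        prof[10:30] = 3.0
        prof[25:45] = 4.0  # overlapping, stronger
        regions = locate_anchor_domains(prof, n_domains=2, threshold=2.0)
        assert len(regions) == 1  # the merged run is one region
        assert regions[0].start == 10 and regions[0].end == 45

    def test_family_profile_shows_n_terminal_anchors(self, families5):
        seqs, truth = families5
        ids = sorted(m for m, f in truth.members.items() if f == "pMULT1")
        prof = windowed_conservation([seqs[i] for i in ids], window=15)
        regions = locate_anchor_domains(prof, n_domains=3)
        assert regions, "conserved anchor domains should stand out"
        assert any(r.start < 60 for r in regions)  # N1/N2 territory


class TestDifferentialConservation:
    def test_identical_partner_groups_have_no_signature(self):
        ab1, _, _ = fixtures.make_signature_alignments(2)
        assert differential_conservation(ab1, ab1) == []

    def test_planted_block_is_single_region(self):
        ab1, ab2, _ = fixtures.make_signature_alignments(2)
        regions = differential_conservation(ab1, ab2)
        assert len(regions) == 1
        blk = fixtures.SIGNATURE_BLOCK
        assert regions[0].start <= blk[0] and regions[0].end >= blk[1]
        assert len(regions[0].consensus) == regions[0].end - regions[0].start

    def test_threshold_above_maximum_difference_returns_nothing(self):
        ab1, ab2, _ = fixtures.make_signature_alignments(2)
        assert differential_conservation(ab1, ab2, delta_min=50.0) == []

    def test_antisymmetry_under_group_swap(self):
        ab1, ab2, _ = fixtures.make_signature_alignments(2)
        from mulescan.conservation import _project_to_reference
        ref = sorted(set(ab1.ids) & set(ab2.ids))[0]
        p1 = _project_to_reference(ab1, windowed_conservation(ab1, 10), ref)
        p2 = _project_to_reference(ab2, windowed_conservation(ab2, 10), ref)
        d12, d21 = p1 - p2, p2 - p1
        assert np.allclose(d12, -d21, equal_nan=True)

    def test_disjoint_alignments_rejected(self):
        a = AlignmentBlock(ids=["x"], rows=["ACD"])
        b = AlignmentBlock(ids=["y"], rows=["ACD"])
        with pytest.raises(ValueError):
            differential_conservation(a, b)
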