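"""Split-read extraction, cut-point detection, deletion-pattern inference,
extent summaries and gene-overlap accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cas3audit import deletion_analysis as da
from cas3audit.genome_io import GeneAnnotation, GenomicInterval

from conftest import make_pair, make_record


def evidence(breakpoints, contig="chr1"):
    return [
        da.SplitReadEvidence(f"e{i}", contig, "right", bp, 30)
        for i, bp in enumerate(breakpoints)
    ]


def pattern(left, right, contig="chr1", pairs=10):
    return da.DeletionPattern(
        del_interval=GenomicInterval(contig, left, right),
        left_bp=left,
        right_bp=right,
        n_supporting_pairs=pairs,
        n_supporting_splits=0,
    )


class TestExtractSplitReads:
    def test_right_clip_breakpoint(self):
        rec = make_record(pos=1000, cigar=(("M", 70), ("S", 30)))
        (ev,) = da.extract_split_reads([rec], min_clip=20)
        assert (ev.clip_side, ev.breakpoint, ev.clip_len) == ("right", 1070, 30)

    def test_left_clip_breakpoint(self):
        rec = make_record(pos=500, cigar=(("S", 25), ("M", 75)))
        (ev,) = da.extract_split_reads([rec], min_clip=20)
        assert (ev.clip_side, ev.breakpoint, ev.clip_len) == ("left", 500, 25)

    def test_short_clip_ignored(self):
        rec = make_record(pos=0, cigar=(("M", 90), ("S", 10)))
        assert da.extract_split_reads([rec], min_clip=20) == []

    def test_both_ends_yield_two_items(self):
        rec = make_record(pos=100, cigar=(("S", 20), ("M", 60), ("S", 20)))
        out = da.extract_split_reads([rec], min_clip=20)
        assert {(e.clip_side, e.breakpoint) for e in out} == {
            ("left", 100),
            ("right", 160),
        }

    def test_quality_filters(self):
        low_mapq = make_record(pos=0, cigar=(("M", 50), ("S", 50)), mapq=5)
        secondary = make_record(pos=0, cigar=(("M", 50), ("S", 50)), secondary=True)
        unmapped = make_record(pos=0, cigar=(), unmapped=True)
        assert da.extract_split_reads([low_mapq, secondary, unmapped]) == []


class TestDiscordantPairs:
    def test_normal_fr_pair_not_discordant(self):
        recs = make_pair("p", "chr1", 1000, 1200)  # tlen 350
        assert da.extract_discordant_pairs(recs, tlen_threshold=1000) == []

    def test_deletion_spanning_pair(self):
        # mates flank a 50-kb deletion starting near 10_000
        recs = make_pair("p", "chr1", 9800, 60_050)
        (pair,) = da.extract_discordant_pairs(recs, tlen_threshold=1000)
        assert pair.span.start == 9950  # left mate reference end
        assert pair.span.end == 60_050  # right mate start
        assert pair.orientation == "FR"

    def test_rf_orientation_discordant_despite_small_tlen(self):
        recs = make_pair("p", "chr1", 1000, 1200, left_strand="-", right_strand="+")
        (pair,) = da.extract_discordant_pairs(recs, tlen_threshold=1000)
        assert pair.orientation == "RF"

    def test_missing_mate_dropped(self, caplog):
        recs = make_pair("p", "chr1", 9800, 60_050)[:1]
        assert da.extract_discordant_pairs(recs, tlen_threshold=1000) == []

    def test_insert_stats_from_proper_pairs(self):
        recs = []
        for i, gap in enumerate([100, 120, 80, 100]):
            left = 1000 + 500 * i
            a, b = make_pair(f"p{i}", "chr1", left, left + 150 + gap)
            a.is_proper_pair = b.is_proper_pair = True
            recs += [a, b]
        mean, sd = da.estimate_insert_stats(recs)
        assert mean == pytest.approx(400, abs=1)
        assert sd == pytest.approx(np.std([400, 420, 380, 400]), abs=1)


class TestBinning:
    def test_counts_per_bin(self):
        region = GenomicInterval("chr1", 1000, 1200)
        bins = da.bin_split_counts(
            evidence([1010, 1020, 1090, 1150, 1160]), [], region, bin_width=100
        )
        assert [b.treated_count for b in bins] == [3, 2]
        assert [b.control_count for b in bins] == [0, 0]

    def test_empty_evidence_all_zero(self):
        region = GenomicInterval("chr1", 0, 1000)
        bins = da.bin_split_counts([], [], region, bin_width=100)
        assert all(b.treated_count == 0 and b.control_count == 0 for b in bins)

    def test_conservation_random_evidence(self):
        rng = np.random.default_rng(42)
        region = GenomicInterval("chr1", 5000, 9000)
        bps = rng.integers(0, 12_000, 500)  # some outside the region
        ev = evidence(bps.tolist())
        bins = da.bin_split_counts(ev, ev, region, bin_width=100)
        inside = int(((bps >= 5000) & (bps < 9000)).sum())
        assert sum(b.treated_count for b in bins) == inside
        assert sum(b.control_count for b in bins) == inside


class TestCutPoints:
    def _bin(self, treated, control, start=0):
        return da.BinCounts(GenomicInterval("chr1", start, start + 100), treated, control)

    def test_ratio_above_threshold(self):
        assert len(da.detect_cut_points([self._bin(12, 2)], min_support=3)) == 1

    def test_ratio_exactly_threshold_rejected(self):
        assert da.detect_cut_points([self._bin(10, 2)], min_support=3) == []

    def test_zero_control_uses_pseudo_denominator(self):
        (cp,) = da.detect_cut_points([self._bin(8, 0)], min_support=3)
        assert cp.ratio == 8.0

    def test_min_support_applies(self):
        assert da.detect_cut_points([self._bin(2, 0)], min_support=3) == []

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=1,
            max_size=30,
        ),
        st.floats(1.0, 20.0),
        st.floats(0.0, 30.0),
    )
    def test_monotone_in_threshold(self, counts, low, extra):
        bins = [
            da.BinCounts(GenomicInterval("c", 100 * i, 100 * i + 100), t, c)
            for i, (t, c) in enumerate(counts)
        ]
        at_low = {cp.bin.start for cp in da.detect_cut_points(bins, low, 1)}
        at_high = {cp.bin.start for cp in da.detect_cut_points(bins, low + extra, 1)}
        assert at_high <= at_low


class TestInferPatterns:
    def _cut_point(self, pos):
        return da.CutPoint(GenomicInterval("chr1", pos - 50, pos + 50), 10.0, 20)

    def test_single_deletion_recovered(self):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(10):
            gap = int(rng.integers(0, 80))
            recs = make_pair(f"p{i}", "chr1", 10_000 - 150 - gap, 60_000 + gap)
            pairs += da.extract_discordant_pairs(recs, tlen_threshold=1000)
        (pat,) = da.infer_deletion_patterns(
            [self._cut_point(10_000)], pairs, [], merge_tol=150
        )
        assert abs(pat.left_bp - 10_000) <= 150
        assert abs(pat.right_bp - 60_000) <= 150
        assert pat.n_supporting_pairs == 10

    def test_two_deletions_sharing_left_breakpoint(self):
        rng = np.random.default_rng(1)
        pairs = []
        for far_i, far in enumerate([40_000, 70_000]):
            for i in range(6):
                gap = int(rng.integers(0, 80))
                recs = make_pair(
                    f"p{far_i}_{i}", "chr1", 10_000 - 150 - gap, far + gap
                )
                pairs += da.extract_discordant_pairs(recs, tlen_threshold=1000)
        pats = da.infer_deletion_patterns(
            [self._cut_point(10_000)], pairs, [], merge_tol=150
        )
        assert len(pats) == 2
        assert {round(p.right_bp, -3) for p in pats} == {40_000, 70_000}

    def test_no_pairs_no_patterns(self):
        assert da.infer_deletion_patterns([self._cut_point(10_000)], [], [], 150) == []

    def test_supporting_splits_counted(self):
        recs = []
        for i in range(6):
            recs += make_pair(f"p{i}", "chr1", 9_850, 60_000)
        pairs = da.extract_discordant_pairs(recs, tlen_threshold=1000)
        splits = evidence([10_000, 10_010, 59_990, 45_000])
        (pat,) = da.infer_deletion_patterns(
            [self._cut_point(10_000)], pairs, splits, merge_tol=150
        )
        assert pat.n_supporting_splits == 3


class TestExtents:
    PAM = GenomicInterval("chr1", 100_000, 100_035, "+")

    def test_single_downstream_pattern(self):
        s = da.summarize_extents([pattern(100_000, 105_000)], self.PAM)
        assert (s.max_3p_extent, s.max_5p_extent, s.n_patterns) == (5000, 0, 1)

    def test_max_over_patterns(self):
        pats = [pattern(100_000, 100_000 + x) for x in (1000, 40_000, 7000)]
        s = da.summarize_extents(pats, self.PAM)
        assert s.max_3p_extent == 40_000

    def test_minus_strand_pam_swaps_directions(self):
        pam = GenomicInterval("chr1", 100_000, 100_035, "-")
        s = da.summarize_extents([pattern(100_035, 105_000)], pam)
        assert (s.max_3p_extent, s.max_5p_extent) == (0, 4965)

    def test_empty_patterns(self):
        s = da.summarize_extents([], self.PAM)
        assert (s.max_3p_extent, s.max_5p_extent, s.n_patterns) == (0, 0, 0)


class TestGeneOverlap:
    GENE = GeneAnnotation("DAD1", GenomicInterval("chr1", 200_000, 210_000, "+"))

    def _patterns(self, n_overlap, n_total):
        pats = [pattern(199_000, 205_000) for _ in range(n_overlap)]
        pats += [pattern(50_000, 60_000) for _ in range(n_total - n_overlap)]
        return pats

    @pytest.mark.parametrize(
        "n_overlap,n_total,expected",
        [(8, 154, 5.2), (65, 746, 8.7), (0, 100, 0.0)],
    )
    def test_percentages(self, n_overlap, n_total, expected):
        (summary,) = da.annotate_gene_overlap(
            self._patterns(n_overlap, n_total), [self.GENE]
        )
        assert summary.n_overlapping == n_overlap
        assert summary.n_total == n_total
        assert summary.percent_1dp == expected

    def test_partial_vs_full_containment(self):
        pats = [pattern(199_000, 205_000), pattern(195_000, 215_000)]
        (summary,) = da.annotate_gene_overlap(pats, [self.GENE])
        assert summary.n_overlapping == 2
        assert summary.n_partial == 1

    def test_empty_patterns_explicit_empty(self):
        assert da.annotate_gene_overlap([], [self.GENE]) == []
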