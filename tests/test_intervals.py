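"""Interval algebra: overlap semantics, intersection, annotation, correlation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetome.intervals import (
    EmptyQueryError,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    RegionSet,
    ZeroVarianceError,
    annotate_nearest_tss,
    classify_position,
    height_correlation,
    intersect_peaksets,
    overlap_fraction,
    overlaps,
)

from conftest import random_peakset
from oracles import brute_nearest_gene, brute_overlap_flags, brute_overlaps, brute_shared_peaks


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestOverlaps:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (iv(100, 200), iv(199, 300), True),   # one shared base
            (iv(100, 200), iv(200, 300), False),  # half-open abutment
            (iv(100, 200), iv(100, 200), True),   # identity
            (iv(100, 200), iv(150, 160), True),   # containment
            (iv(100, 200), iv(100, 200, "chr2"), False),
        ],
    )
    def test_one_shared_nucleotide_semantics(self, a, b, expected):
        assert overlaps(a, b) is expected

    @given(
        s1=st.integers(0, 500), w1=st.integers(1, 100),
        s2=st.integers(0, 500), w2=st.integers(1, 100),
    )
    def test_symmetry_and_oracle_equivalence(self, s1, w1, s2, w2):
        a, b = iv(s1, s1 + w1), iv(s2, s2 + w2)
        assert overlaps(a, b) == overlaps(b, a) == brute_overlaps(a, b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 1)


class TestIntersectPeaksets:
    def test_disjoint_sets_share_nothing(self):
        r1 = PeakSet([Peak(iv(0, 100))])
        r2 = PeakSet([Peak(iv(200, 300))])
        hc, rep = intersect_peaksets(r1, r2)
        assert len(hc) == 0 and rep.shared == 0

    def test_identical_sets_fully_concordant(self):
        peaks = [Peak(iv(i * 100, i * 100 + 50), name=f"x{i}") for i in range(5)]
        hc, rep = intersect_peaksets(PeakSet(peaks), PeakSet(peaks))
        assert rep.shared == 5
        assert rep.concordance1 == rep.concordance2 == 1.0
        assert rep.mean_concordance == 1.0
        # replicate-1 intervals are retained as the high-confidence peaks
        assert [p.name for p in hc] == [f"x{i}" for i in range(5)]

    def test_each_replicate1_peak_counted_once(self):
        r1 = PeakSet([Peak(iv(100, 200))])
        r2 = PeakSet([Peak(iv(90, 120)), Peak(iv(150, 250))])
        hc, rep = intersect_peaksets(r1, r2)
        assert rep.shared == 1 and len(hc) == 1

    def test_largest_overlap_mate_ties_leftmost(self):
        r1 = PeakSet([Peak(iv(100, 200))])
        # both mates overlap by 30 bp; the leftmost wins
        r2 = PeakSet([Peak(iv(170, 230), name="right"), Peak(iv(70, 130), name="left")])
        _, rep = intersect_peaksets(r1, r2)
        assert rep.pairs == [(0, 1)]
        assert r2[rep.pairs[0][1]].name == "left"

    def test_empty_input_flagged(self):
        _, rep = intersect_peaksets(PeakSet(), PeakSet([Peak(iv(0, 10))]))
        assert rep.empty_input and rep.shared == 0 and rep.mean_concordance == 0.0

    def test_matches_all_pairs_oracle_on_random_sets(self, rng):
        for _ in range(20):
            r1 = random_peakset(rng, int(rng.integers(5, 120)))
            r2 = random_peakset(rng, int(rng.integers(5, 120)), prefix="q")
            hc, rep = intersect_peaksets(r1, r2)
            assert rep.shared == len(brute_shared_peaks(r1, r2))
            assert len(hc) == rep.shared


class TestOverlapFraction:
    def test_empty_reference_gives_zero(self):
        q = PeakSet([Peak(iv(0, 10)), Peak(iv(20, 30))])
        frac, flags = overlap_fraction(q, RegionSet())
        assert frac == 0.0 and not flags.any()

    def test_tiling_reference_gives_one(self):
        q = PeakSet([Peak(iv(i * 50, i * 50 + 10)) for i in range(4)])
        frac, flags = overlap_fraction(q, RegionSet([iv(0, 10_000)]))
        assert frac == 1.0 and flags.all()

    def test_empty_query_is_an_error_not_zero(self):
        with pytest.raises(EmptyQueryError):
            overlap_fraction(PeakSet(), RegionSet([iv(0, 10)]))

    def test_fraction_invariant_under_reference_splitting(self):
        # splitting a reference region at a non-peak base changes nothing
        q = PeakSet([Peak(iv(100, 120)), Peak(iv(300, 320)), Peak(iv(900, 920))])
        whole = RegionSet([iv(90, 330)])
        split = RegionSet([iv(90, 200), iv(200, 330)])
        assert overlap_fraction(q, whole)[0] == overlap_fraction(q, split)[0]

    def test_matches_oracle_on_random_sets(self, rng):
        for _ in range(20):
            q = random_peakset(rng, int(rng.integers(3, 80)))
            ref = RegionSet([p.interval for p in random_peakset(rng, int(rng.integers(1, 40)))])
            _, flags = overlap_fraction(q, ref)
            assert flags.tolist() == brute_overlap_flags(q, ref)


class TestAnnotateNearestTss:
    genes = GeneAnnotation([
        Gene("X", "chr1", 1_000_000, "+"),
        Gene("Y", "chr1", 1_400_000, "+"),
    ])

    def test_unique_nearest_with_signed_distance(self):
        peaks = PeakSet([Peak(iv(1_004_975, 1_005_025))])  # midpoint 5 kb 3' of X
        (a,) = annotate_nearest_tss(peaks, self.genes)
        assert a.gene_id == "X" and a.signed_distance == 5_000

    def test_nothing_within_cutoff_is_unassigned(self):
        peaks = PeakSet([Peak(iv(2_000_000, 2_000_050))])
        (a,) = annotate_nearest_tss(peaks, self.genes)
        assert not a.assigned and a.position_class == "unassigned"

    def test_equidistant_tie_breaks_to_smaller_identifier(self):
        genes = GeneAnnotation([
            Gene("B", "chr1", 1_000, "+"),
            Gene("A", "chr1", 3_000, "+"),
        ])
        peaks = PeakSet([Peak(iv(1_975, 2_025))])  # midpoint 2000, 1 kb from each
        (a,) = annotate_nearest_tss(peaks, genes)
        assert a.gene_id == "A"

    def test_minus_strand_flips_the_sign(self):
        genes = GeneAnnotation([Gene("M", "chr1", 50_000, "-")])
        peaks = PeakSet([Peak(iv(54_975, 55_025))])  # 5 kb right of TSS, upstream of M
        (a,) = annotate_nearest_tss(peaks, genes)
        assert a.signed_distance == -5_000
        assert a.position_class == "distal_upstream"

    def test_summit_preferred_over_midpoint(self):
        peaks = PeakSet([Peak(iv(0, 100_000), summit=99_000)])
        genes = GeneAnnotation([Gene("S", "chr1", 100_000, "+")])
        (a,) = annotate_nearest_tss(peaks, genes)
        assert a.signed_distance == -1_000

    def test_matches_full_scan_oracle(self, rng):
        genes = [
            Gene(f"G{i:02d}", f"chr{1 + i % 2}", int(rng.integers(0, 500_000)),
                 "+" if rng.random() < 0.5 else "-")
            for i in range(30)
        ]
        ann = GeneAnnotation(genes)
        peaks = random_peakset(rng, 200, n_chroms=2, span=600_000)
        for p, a in zip(peaks, annotate_nearest_tss(peaks, ann)):
            gid, sd = brute_nearest_gene(p.interval.chrom, p.reference_point,
                                         genes, 100_000)
            assert (a.gene_id, a.signed_distance) == (gid, sd)


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (0, "proximal"),
            (-1_000, "proximal"),
            (1_000, "proximal"),          # inclusive boundary
            (-1_001, "distal_upstream"),
            (-50_000, "distal_upstream"),
            (-100_000, "distal_upstream"),
            (1_001, "distal_downstream"),
            (100_000, "distal_downstream"),
            (100_001, "unassigned"),
            (-100_001, "unassigned"),
        ],
    )
    def test_bin_boundaries(self, d, expected):
        assert classify_position(d) == expected

    @given(st.integers(-100_000, 100_000))
    def test_classes_partition_the_assigned_range(self, d):
        assert classify_position(d) in ("proximal", "distal_upstream", "distal_downstream")


class TestHeightCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, r2 = height_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and r2 == 1.0

    def test_hand_computed_value(self):
        # cov = 0.75, var_x = var_y = 1.25 -> r = 0.6
        r, r2 = height_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6) and r2 == 0.6

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ZeroVarianceError):
            height_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            height_correlation([1, 2], [1, 2])
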