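"""Planted-structure generators: quota exactness, determinism, recoverability."""

import numpy as np
import pytest

from targetome.intervals import PeakSet, intersect_peaksets, overlap_fraction
from targetome.motifs import Motif, scan_consensus
from targetome.synthetic import (
    ExpressionTruth,
    FixtureSpec,
    GenomeModel,
    GenomeTooSmallError,
    NestingError,
    generate_expression_matrix,
    generate_gene_annotation,
    generate_paired_heights,
    generate_region_set_with_quota,
    generate_replicate_peaksets,
    generate_sequences,
    genome_for,
)
from targetome.utils import largest_remainder_counts

from oracles import brute_overlap_flags


def small_spec(**kw):
    base = dict(n1=60, n2=70, k=50, n_genes=30, seed=11)
    base.update(kw)
    return FixtureSpec(**base)


class TestGeneAnnotation:
    def test_spacing_invariant_holds(self):
        genome = GenomeModel({"chr1": 10_000_000}, spacing=300_000)
        ann = generate_gene_annotation(genome, 10, seed=1)
        tss = sorted(g.tss for g in ann)
        gaps = np.diff(tss)
        assert len(ann) == 10 and (gaps >= 300_000).all()

    def test_empty_annotation_is_valid(self):
        genome = GenomeModel({"chr1": 1_000_000})
        assert len(generate_gene_annotation(genome, 0, seed=1)) == 0

    def test_too_small_genome_names_the_deficit(self):
        genome = GenomeModel({"chr1": 1_000_000})
        with pytest.raises(GenomeTooSmallError, match="genes"):
            generate_gene_annotation(genome, 50, seed=1)

    def test_deterministic_per_seed(self):
        genome = GenomeModel({"chr1": 20_000_000})
        a = generate_gene_annotation(genome, 20, seed=5)
        b = generate_gene_annotation(genome, 20, seed=5)
        assert [(g.gene_id, g.tss, g.strand) for g in a] == [
            (g.gene_id, g.tss, g.strand) for g in b
        ]

    def test_spacing_floor_enforced(self):
        with pytest.raises(ValueError, match="spacing"):
            GenomeModel({"chr1": 10_000_000}, spacing=100_000)


class TestReplicatePeaksets:
    def test_all_shared_identity_case(self):
        spec = small_spec(n1=3, n2=3, k=3, n_genes=1)
        ann = generate_gene_annotation(genome_for(spec, n_genes=1), 1, seed=2)
        r1, r2, planted = generate_replicate_peaksets(spec, ann, seed=2)
        _, rep = intersect_peaksets(r1, r2)
        assert rep.shared == 3
        assert rep.concordance1 == rep.concordance2 == 1.0

    def test_zero_shared_means_empty_intersection(self):
        spec = small_spec(n1=20, n2=25, k=0, n_genes=0)
        ann = generate_gene_annotation(genome_for(spec, n_genes=5), 5, seed=3)
        r1, r2, planted = generate_replicate_peaksets(spec, ann, seed=3)
        _, rep = intersect_peaksets(r1, r2)
        assert rep.shared == 0 and planted == []

    def test_intersection_recovers_exactly_k(self):
        spec = small_spec()
        ann = generate_gene_annotation(genome_for(spec), spec.n_genes, seed=4)
        r1, r2, _ = generate_replicate_peaksets(spec, ann, seed=4)
        assert (len(r1), len(r2)) == (60, 70)
        _, rep = intersect_peaksets(r1, r2)
        assert rep.shared == 50

    def test_planted_gene_map_recovered_by_nearest_tss(self):
        from targetome.intervals import annotate_nearest_tss

        spec = small_spec()
        ann = generate_gene_annotation(genome_for(spec), spec.n_genes, seed=6)
        r1, r2, planted = generate_replicate_peaksets(spec, ann, seed=6)
        hc, _ = intersect_peaksets(r1, r2)
        annotations = annotate_nearest_tss(hc, ann)
        assert len({p.gene_id for p in planted}) == spec.n_genes
        for p, a in zip(planted, annotations):
            assert a.gene_id == p.gene_id
            assert a.position_class == p.category

    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        from targetome.io import write_bed

        spec = small_spec()
        ann = generate_gene_annotation(genome_for(spec), spec.n_genes, seed=7)
        files = []
        for run in ("a", "b"):
            r1, _, _ = generate_replicate_peaksets(spec, ann, seed=99)
            path = tmp_path / f"{run}.bed"
            write_bed(r1, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError, match="replicate size"):
            FixtureSpec(n1=10, n2=10, k=11, n_genes=5)
        with pytest.raises(ValueError, match="nest"):
            small_spec(dhs_quota_up=30.0, cofactor_quota_up=40.0)
        with pytest.raises(ValueError, match="sum"):
            small_spec(positional_quota_up=(50, 50, 50))


class TestRegionQuota:
    def make_targets(self, n, seed=0):
        spec = small_spec(n1=n, n2=n, k=n, n_genes=n)
        ann = generate_gene_annotation(genome_for(spec), n, seed=seed)
        r1, _, _ = generate_replicate_peaksets(spec, ann, seed=seed)
        return PeakSet(list(r1)[:n])

    def test_zero_quota_touches_nothing(self):
        targets = self.make_targets(20)
        regions = generate_region_set_with_quota(targets, 0, seed=1)
        assert not any(brute_overlap_flags(targets, regions))

    def test_full_quota_touches_everything(self):
        targets = self.make_targets(20)
        regions = generate_region_set_with_quota(targets, 100, seed=1)
        assert all(brute_overlap_flags(targets, regions))

    @pytest.mark.parametrize("fraction, n, expected", [(69, 200, 138), (50, 30, 15), (37, 40, 15)])
    def test_exact_quota_arithmetic_verified_by_all_pairs(self, fraction, n, expected):
        targets = self.make_targets(n, seed=fraction)
        regions = generate_region_set_with_quota(targets, fraction, seed=2)
        assert sum(brute_overlap_flags(targets, regions)) == expected

    def test_nesting_constrains_the_chosen_subset(self):
        targets = self.make_targets(40)
        parent = generate_region_set_with_quota(targets, 50, seed=3)
        child = generate_region_set_with_quota(targets, 25, seed=4, nested_within=parent)
        _, parent_flags = overlap_fraction(targets, parent)
        _, child_flags = overlap_fraction(targets, child)
        assert child_flags.sum() == 10
        assert not (child_flags & ~parent_flags).any()

    def test_infeasible_nesting_raises(self):
        targets = self.make_targets(40)
        parent = generate_region_set_with_quota(targets, 10, seed=5)
        with pytest.raises(NestingError):
            generate_region_set_with_quota(targets, 50, seed=6, nested_within=parent)


class TestLargestRemainder:
    def test_printed_percentages_recoverable(self):
        assert largest_remainder_counts((14, 23, 63), 1000, warn=False) == [140, 230, 630]
        assert largest_remainder_counts((9, 27, 64), 1000, warn=False) == [90, 270, 640]

    def test_non_integral_shares_warn_and_sum(self):
        with pytest.warns(UserWarning, match="largest remainder"):
            counts = largest_remainder_counts((14, 23, 63), 37)
        assert sum(counts) == 37

    @pytest.mark.parametrize("n", [0, 1, 7, 99, 1000])
    def test_counts_always_sum_to_n(self, n):
        assert sum(largest_remainder_counts((9, 27, 64), n, warn=False)) == n


class TestPairedHeights:
    def test_perfect_correlation_is_exact(self):
        from targetome.intervals import height_correlation

        h1, h2 = generate_paired_heights(100, 1.0, seed=0)
        assert height_correlation(h1, h2)[1] == 1.0

    def test_null_correlation_stays_small(self):
        from targetome.intervals import height_correlation

        h1, h2 = generate_paired_heights(10_000, 0.0, seed=1)
        assert abs(height_correlation(h1, h2)[0]) < 0.05

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            generate_paired_heights(2, 0.5)
        with pytest.raises(ValueError):
            generate_paired_heights(10, 1.5)

    def test_heights_nonnegative(self):
        h1, h2 = generate_paired_heights(5_000, 0.91, seed=2)
        assert (h1 >= 0).all() and (h2 >= 0).all()


class TestExpressionGenerator:
    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            ExpressionTruth.planted(10, 1, 1, sigma=0.0)

    def test_truth_label_counts_match_plan(self):
        truth = ExpressionTruth.planted(100, 7, 5)
        assert len(truth.up_probes) == 7 and len(truth.down_probes) == 5

    def test_matrix_encodes_effects(self):
        truth = ExpressionTruth.planted(50, 5, 5, effect=3.0, sigma=0.01)
        matrix, groups = generate_expression_matrix(truth, seed=0)
        treated = [s for s, g in groups.items() if g == "treated"]
        control = [s for s, g in groups.items() if g == "control"]
        diff = matrix[treated].mean(axis=1) - matrix[control].mean(axis=1)
        assert diff.iloc[:5].min() > 2.5 and abs(diff.iloc[10:].mean()) < 0.1

    def test_deterministic_per_seed(self):
        truth = ExpressionTruth.planted(20, 2, 2)
        m1, _ = generate_expression_matrix(truth, seed=3)
        m2, _ = generate_expression_matrix(truth, seed=3)
        assert m1.equals(m2)


class TestSequenceGenerator:
    nbre = Motif("NBRE", "AAAGGTCA")

    def test_zero_plantings_scan_zero(self):
        records = generate_sequences([f"w{i}" for i in range(20)], [0] * 20,
                                     self.nbre, seed=0)
        assert sum(scan_consensus(seq, self.nbre) for _, seq in records) == 0

    def test_one_planting_per_window_scans_to_total(self):
        n = 50
        records = generate_sequences([f"w{i}" for i in range(n)], [1] * n,
                                     self.nbre, seed=1)
        counts = [scan_consensus(seq, self.nbre) for _, seq in records]
        assert counts == [1] * n

    def test_overfull_window_rejected(self):
        with pytest.raises(ValueError, match="plant"):
            generate_sequences(["w"], [50], self.nbre, seed=0)

    def test_windows_are_fixed_width_acgt(self):
        records = generate_sequences(["w1", "w2"], [2, 0], self.nbre, seed=2)
        for _, seq in records:
            assert len(seq) == 300 and set(seq) <= set("ACGT")
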