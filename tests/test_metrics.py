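"""Metric arithmetic: depth filter, R, Jaccard, precision/recall/F, tables."""

import math

import numpy as np
import pytest

from hrrforge.metrics import (
    auto_max_depth,
    avg_jaccard,
    depth_filter,
    jaccard,
    precision_recall_f,
    reproducibility,
    reproducibility_table,
    stratify,
)
from hrrforge.model import (
    CallSet,
    ComparisonCounts,
    ConfigurationError,
    FactorLabels,
    GenomicInterval,
    RegionSet,
    VariantCall,
    match_callsets,
)
from conftest import callset_at, snv


def dp_set(depths):
    return CallSet(
        [snv(10 * (i + 1), dp=d) for i, d in enumerate(depths)], sample="S"
    )


class TestDepthFilter:
    def test_inclusive_bounds(self):
        out = depth_filter(dp_set([5, 8, 10, 300]), min_dp=8, max_dp=223)
        assert sorted(v.depth for v in out) == [8, 10]

    def test_auto_max_with_constant_depth(self):
        cs = dp_set([30] * 6)
        assert auto_max_depth(cs) == 30
        assert len(depth_filter(cs, min_dp=8, max_dp="auto")) == 6

    def test_auto_max_removes_only_outliers_beyond_mean_plus_3sd(self):
        depths = [20] * 50 + [22] * 50 + [500]
        cs = dp_set(depths)
        arr = np.array(depths, dtype=float)
        cutoff = round(arr.mean() + 3 * arr.std())
        out = depth_filter(cs, min_dp=0, max_dp="auto")
        expected = [d for d in depths if d <= cutoff]
        assert sorted(v.depth for v in out) == sorted(expected)

    def test_missing_dp_retained(self):
        cs = CallSet([snv(10, dp=None), snv(20, dp=3)], sample="S")
        out = depth_filter(cs, min_dp=8, max_dp=100)
        assert [v.depth for v in out] == [None]

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            depth_filter(dp_set([10]), min_dp=50, max_dp=10)

    def test_size_matches_brute_force(self):
        rng = np.random.default_rng(12)
        depths = rng.integers(1, 100, size=200).tolist()
        out = depth_filter(dp_set(depths), min_dp=8, max_dp=60)
        assert len(out) == sum(8 <= d <= 60 for d in depths)


class TestReproducibility:
    def test_eq1_arithmetic(self):
        assert reproducibility(ComparisonCounts(4, 4, 3, 3)) == 0.75

    def test_identical_sets_r_one(self):
        a = callset_at([1, 2, 3])
        assert reproducibility(match_callsets(a, a).counts) == 1.0

    def test_disjoint_sets_r_zero(self):
        r = reproducibility(match_callsets(callset_at([1]), callset_at([2])).counts)
        assert r == 0.0

    def test_empty_side_is_missing_not_zero(self):
        assert math.isnan(reproducibility(ComparisonCounts(0, 5, 0, 0)))

    def test_asymmetric_sizes(self):
        # n/N differ per side: R = (2/4 + 2/8)/2
        c = ComparisonCounts(N_a=4, N_b=8, n_a=2, n_b=2)
        assert reproducibility(c) == pytest.approx(0.375)


class TestJaccard:
    def test_avg_jaccard_hand_example(self):
        A, B, C = callset_at([1, 2, 3]), callset_at([2, 3, 4]), callset_at([3, 4, 5])
        assert avg_jaccard(A, B, C) == pytest.approx((0.5 + 0.2 + 0.5) / 3)

    def test_identical_replicates_one(self):
        A = callset_at([1, 2])
        assert avg_jaccard(A, A, A) == 1.0

    def test_pairwise_disjoint_zero(self):
        assert avg_jaccard(callset_at([1]), callset_at([2]), callset_at([3])) == 0.0

    def test_empty_pair_dropped_from_mean(self):
        A, B, C = CallSet(), CallSet(), callset_at([1])
        # A∪B empty -> that term missing; remaining terms are 0, 0
        assert avg_jaccard(A, B, C) == 0.0

    def test_all_empty_missing(self):
        assert math.isnan(avg_jaccard(CallSet(), CallSet(), CallSet()))


class TestPrecisionRecallF:
    def test_eq234_arithmetic(self):
        p, r, f = precision_recall_f(ComparisonCounts(N_a=10, N_b=10, n_a=8, n_b=8))
        assert (p, r, f) == (0.8, 0.8, pytest.approx(0.8))

    def test_perfect_agreement(self):
        assert precision_recall_f(ComparisonCounts(5, 5, 5, 5)) == (1.0, 1.0, 1.0)

    def test_zero_common_gives_zero_f(self):
        p, r, f = precision_recall_f(ComparisonCounts(4, 6, 0, 0))
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_empty_truth_missing_recall(self):
        p, r, f = precision_recall_f(ComparisonCounts(4, 0, 0, 0))
        assert p == 0.0 and math.isnan(r) and math.isnan(f)


class TestRandomizedArithmetic:
    def test_metrics_match_brute_force_sets(self):
        """R, Jaccard, PRF from set arithmetic on random call-set pairs;
        Jaccard <= R on every instance."""
        rng = np.random.default_rng(2024)
        for _ in range(150):
            ka = set(map(int, rng.choice(500, size=rng.integers(1, 60), replace=False)))
            kb = set(map(int, rng.choice(500, size=rng.integers(1, 60), replace=False)))
            a, b = callset_at(sorted(ka)), callset_at(sorted(kb))
            m = match_callsets(a, b)
            inter, union = len(ka & kb), len(ka | kb)
            r_expect = 0.5 * (inter / len(ka) + inter / len(kb))
            assert reproducibility(m.counts) == pytest.approx(r_expect)
            assert jaccard(a, b) == pytest.approx(inter / union)
            p, rec, f = precision_recall_f(m.counts)
            assert p == pytest.approx(inter / len(ka))
            assert rec == pytest.approx(inter / len(kb))
            if p + rec > 0:
                assert f == pytest.approx(2 * p * rec / (p + rec))
            assert jaccard(a, b) <= reproducibility(m.counts) + 1e-12


class TestStratify:
    def test_partition_by_class(self):
        calls = CallSet(
            [
                VariantCall("chr1", 10, "A", "G", (0, 1)),
                VariantCall("chr1", 20, "CT", "C", (0, 1)),
                VariantCall("chr1", 30, "T", "TAA", (1, 1)),
                VariantCall("chr1", 40, "CT", "AG", (0, 1)),
            ]
        )
        buckets = stratify(calls)
        assert {vc.value: len(cs) for vc, cs in buckets.items() if len(cs)} == {
            "SNV": 1, "DEL": 1, "INS": 1, "MNV": 1
        }
        from hrrforge.metrics import HEADLINE_CLASSES
        from hrrforge.model import VariantClass

        # the MNV lands outside the three headline classes
        assert ("chr1", 40, "CT", "AG") in buckets[VariantClass.MNV].keys()
        assert VariantClass.MNV not in HEADLINE_CLASSES


def grid_callsets(n_rep=3, n_aln=1, positions=(1, 2, 3)):
    out = []
    for r in range(n_rep):
        for a in range(n_aln):
            lbl = FactorLabels("S", "lab1", "p", "l", f"r{r}", f"aln{a}", "c1")
            out.append(callset_at(positions, sample="S", labels=lbl))
    return out


class TestReproducibilityTable:
    def test_technical_pairing_combinatorics(self):
        recs = reproducibility_table(grid_callsets(n_rep=3), "technical", per_class=False)
        assert len(recs) == 3  # C(3,2) pairs

    def test_aligner_pairing_combinatorics(self):
        recs = reproducibility_table(grid_callsets(n_rep=1, n_aln=4), "aligner", per_class=False)
        assert len(recs) == 6  # C(4,2)

    def test_hrr_doubles_records(self):
        hrr = RegionSet([GenomicInterval("chr1", 0, 100)])
        recs = reproducibility_table(grid_callsets(), "technical", hrr=hrr, per_class=False)
        assert len(recs) == 6
        assert sorted(r.hrr_filtered for r in recs) == [False] * 3 + [True] * 3

    def test_unpaired_group_skipped(self):
        lbl = FactorLabels("S", "lab1", "p", "l", "r1", "alnA", "c1")
        recs = reproducibility_table([callset_at([1], labels=lbl)], "technical")
        assert recs == []

    def test_prf_computed_against_hrvs(self):
        sets = grid_callsets(positions=(1, 2, 3, 4))
        hrvs = {"S": callset_at([1, 2, 3])}
        recs = reproducibility_table(sets, "technical", hrvs=hrvs, per_class=False)
        for r in recs:
            assert r.precision == pytest.approx(0.75)
            assert r.recall == pytest.approx(1.0)
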