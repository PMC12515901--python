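import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedri.partitioning import (
    InsufficientDataError,
    SubgroupSummary,
    fit_age_tree,
    harris_boyd,
    lahti,
    refine_partition,
    subgroup_summaries,
)


def make_summary(n, mean, sd, lo=0, hi=12):
    return SubgroupSummary(
        age_lo_months=lo, age_hi_months=hi, n=n, mean=mean, sd=sd,
        q025=mean - 2 * sd, q500=mean, q975=mean + 2 * sd,
    )


class TestSubgroupSummaries:
    def test_single_record(self):
        (s,) = subgroup_summaries([5], [3.0], [(0, 12)])
        assert (s.n, s.mean, s.sd) == (1, 3.0, 0.0)
        assert s.q025 == s.q500 == s.q975 == 3.0

    def test_hand_worked_statistics(self):
        values = [2, 4, 4, 4, 5, 5, 7, 9]
        (s,) = subgroup_summaries([1] * 8, values, [(0, 12)])
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(2.138, abs=1e-3)  # n-1 denominator

    def test_order_invariance(self, rng):
        ages = rng.integers(0, 48, 100)
        values = rng.normal(10, 2, 100)
        bins = [(0, 24), (24, 48)]
        a = subgroup_summaries(ages, values, bins)
        perm = rng.permutation(100)
        b = subgroup_summaries(ages[perm], values[perm], bins)
        for x, y in zip(a, b):
            assert x.n == y.n
            assert x.mean == pytest.approx(y.mean, rel=1e-12)
            assert x.sd == pytest.approx(y.sd, rel=1e-12)
            assert (x.q025, x.q500, x.q975) == (y.q025, y.q500, y.q975)

    def test_empty_bin_omitted(self):
        out = subgroup_summaries([5, 6], [1.0, 2.0], [(0, 12), (100, 112)])
        assert len(out) == 1


class TestHarrisBoyd:
    def test_identical_subgroups(self):
        r = harris_boyd(make_summary(50, 10, 2), make_summary(50, 10, 2))
        assert r.z == 0.0
        assert r.sd_ratio == 1.0
        assert not (r.split_by_z or r.split_by_sd)

    def test_critical_value_is_three_at_240(self):
        r = harris_boyd(make_summary(120, 10, 2), make_summary(120, 10, 2))
        assert r.z_star == 3.0

    def test_hand_worked_split(self):
        r = harris_boyd(make_summary(100, 10, 2), make_summary(100, 12, 2))
        assert r.z == pytest.approx(-7.071, abs=1e-3)
        assert r.z_star == pytest.approx(2.739, abs=1e-3)
        assert r.split_by_z and not r.split_by_sd

    def test_sd_ratio_rule(self):
        r = harris_boyd(make_summary(50, 10, 1), make_summary(50, 10, 1.6))
        assert r.sd_ratio == pytest.approx(1.6)
        assert r.split_by_sd

    @given(
        st.integers(2, 500), st.integers(2, 500),
        st.floats(-100, 100), st.floats(-100, 100),
        st.floats(0.1, 50), st.floats(0.1, 50),
    )
    def test_antisymmetry(self, n1, n2, m1, m2, s1, s2):
        a = harris_boyd(make_summary(n1, m1, s1), make_summary(n2, m2, s2))
        b = harris_boyd(make_summary(n2, m2, s2), make_summary(n1, m1, s1))
        assert b.z == pytest.approx(-a.z, rel=1e-9)
        assert b.z_star == a.z_star
        assert b.sd_ratio == pytest.approx(a.sd_ratio, rel=1e-12)
        assert (b.split_by_z, b.split_by_sd) == (a.split_by_z, a.split_by_sd)

    def test_z_star_grows_with_combined_n(self):
        stars = [
            harris_boyd(make_summary(n, 0, 1), make_summary(n, 0, 1)).z_star
            for n in (10, 60, 120, 500)
        ]
        assert stars == sorted(stars) and len(set(stars)) == len(stars)

    def test_degenerate_zero_spread(self):
        same = harris_boyd(make_summary(10, 5, 0), make_summary(10, 5, 0))
        assert same.z == 0.0
        diff = harris_boyd(make_summary(10, 5, 0), make_summary(10, 6, 0))
        assert math.isinf(diff.z) and diff.split_by_z

    def test_minimum_subgroup_size(self):
        with pytest.raises(InsufficientDataError):
            harris_boyd(make_summary(1, 5, 0), make_summary(10, 5, 1))


class TestLahti:
    def test_identical_subgroups_merge(self, rng):
        v = rng.normal(0, 1, 1000)
        r = lahti(v, v.copy())
        for p in r.proportions:
            assert p == pytest.approx(2.5, abs=0.5)
        assert not r.split

    def test_shifted_subgroup_splits(self):
        rng = np.random.default_rng(11)
        v1 = rng.normal(0, 1, 500)
        v2 = rng.normal(3, 1, 500)
        r = lahti(v1, v2)
        assert r.proportions[3] >= 4.1  # subgroup2 above the common upper limit
        assert r.split

    def test_proportions_match_brute_force_count(self, rng):
        for _ in range(5):
            v1 = rng.lognormal(0, 0.5, 120)
            v2 = rng.lognormal(0.2, 0.5, 80)
            r = lahti(v1, v2)
            expect = (
                100 * np.sum(v1 < r.common_lower) / v1.size,
                100 * np.sum(v1 > r.common_upper) / v1.size,
                100 * np.sum(v2 < r.common_lower) / v2.size,
                100 * np.sum(v2 > r.common_upper) / v2.size,
            )
            assert r.proportions == pytest.approx(expect, abs=1e-12)

    def test_affine_equivariance(self, rng):
        v1 = rng.normal(5, 1, 200)
        v2 = rng.normal(5.5, 1.2, 300)
        a = lahti(v1, v2)
        b = lahti(3.0 * v1 + 10.0, 3.0 * v2 + 10.0)
        assert b.proportions == pytest.approx(a.proportions, abs=1e-12)
        assert b.split == a.split

    def test_minimum_subgroup_size(self):
        with pytest.raises(InsufficientDataError):
            lahti(np.ones(19), np.ones(100))


class TestAgeTree:
    def test_constant_values_never_split(self):
        ages = np.arange(200)
        assert fit_age_tree(ages, np.full(200, 3.0), min_leaf=10) == []

    def test_too_few_records_never_split(self, rng):
        assert fit_age_tree([1, 2, 3], rng.normal(size=3), min_leaf=50) == []

    def test_step_data_root_cut_at_changepoint(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(0, 120, 1000)
        values = np.where(ages < 60, 10.0, 20.0) + rng.standard_normal(1000)
        (root,) = fit_age_tree(ages, values, max_depth=1, min_leaf=50)
        assert 54 <= root <= 66
        # the depth-2 cut set contains the dominant boundary
        cuts = fit_age_tree(ages, values, max_depth=2, min_leaf=50)
        assert any(54 <= c <= 66 for c in cuts) and len(cuts) <= 3

    def test_min_leaf_respected(self, rng):
        ages = rng.integers(0, 100, 300)
        values = rng.normal(size=300) + (ages > 50) * 5
        for cut in fit_age_tree(ages, values, max_depth=2, min_leaf=40):
            assert (ages < cut).sum() >= 40
            assert (ages >= cut).sum() >= 40

    def test_first_cut_matches_exhaustive_scan(self, rng):
        def brute_force_first_cut(ages, values, min_leaf):
            best = None
            thresholds = [
                (a + b) / 2
                for a, b in zip(sorted(set(ages)), sorted(set(ages))[1:])
            ]
            for thr in thresholds:
                left = values[ages < thr]
                right = values[ages >= thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                sse = sum((values - values.mean()) ** 2)
                gain = sse - sum((left - left.mean()) ** 2) - sum(
                    (right - right.mean()) ** 2
                )
                if best is None or gain > best[0] + 1e-9:
                    best = (gain, thr)
            return None if best is None or best[0] <= 1e-9 else best[1]

        for trial in range(10):
            n = int(rng.integers(30, 200))
            ages = rng.integers(0, 60, n)
            values = rng.normal(size=n) + (ages > rng.integers(10, 50)) * 2.0
            expected = brute_force_first_cut(ages, values, min_leaf=5)
            got = fit_age_tree(ages, values, max_depth=1, min_leaf=5)
            if expected is None:
                assert got == []
            else:
                assert got[0] == pytest.approx(expected)

    def test_first_cut_matches_sklearn_cart(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(17)
        for _ in range(5):
            ages = rng.integers(0, 120, 400).astype(float)
            values = rng.normal(size=400) + (ages > 60) * 3.0
            (root,) = fit_age_tree(ages, values, max_depth=1, min_leaf=20)
            t = sklearn.DecisionTreeRegressor(max_depth=1, min_samples_leaf=20)
            t.fit(ages.reshape(-1, 1), values)
            assert root == pytest.approx(t.tree_.threshold[0], abs=1e-9)


class TestRefinePartition:
    def test_homogeneous_data_collapses_to_one_bin(self):
        rng = np.random.default_rng(5)
        ages = rng.integers(0, 121, 2000)
        values = 10.0 + rng.standard_normal(2000)
        cuts = fit_age_tree(ages, values, max_depth=2, min_leaf=50)
        part = refine_partition(ages, values, cuts, min_leaf=50)
        assert part.bins == [(0, int(ages.max()) + 1)]

    def test_two_regime_data_recovers_single_boundary(self):
        rng = np.random.default_rng(3)
        ages = rng.integers(0, 121, 1000)
        values = np.where(ages < 60, 10.0, 13.0) + rng.standard_normal(1000)
        cuts = fit_age_tree(ages, values, max_depth=2, min_leaf=50)
        part = refine_partition(ages, values, cuts, min_leaf=50)
        interior = [b[0] for b in part.bins[1:]]
        assert len(interior) == 1
        assert 54 <= interior[0] <= 66

    def test_structural_invariants_and_audit(self, rng):
        ages = rng.integers(0, 200, 1500)
        values = rng.normal(10, 1, 1500) + (ages > 90) * 2.0
        cuts = fit_age_tree(ages, values, max_depth=2, min_leaf=50)
        part = refine_partition(ages, values, cuts, min_leaf=50)
        # disjoint, contiguous, covering the observed span
        assert part.bins[0][0] == ages.min()
        assert part.bins[-1][1] == ages.max() + 1
        for left, right in zip(part.bins, part.bins[1:]):
            assert left[1] == right[0]
        for lo, hi in part.bins:
            assert ((ages >= lo) & (ages < hi)).sum() >= 50
        assert len(part.decisions) >= len(part.bins) - 1

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            refine_partition(np.array([]), np.array([]), [])
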