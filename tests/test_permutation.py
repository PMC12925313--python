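"""Median-difference permutation test: exactness, calibration, symmetry."""

from math import comb

import numpy as np
import pytest

from _oracles import enumeration_p_value as enumeration_oracle
from glycopan import permutation as perm


class TestExactMode:
    def test_identical_groups_give_p_one(self):
        res = perm.permutation_test_median_diff([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert res.exact

    def test_separated_groups_enumeration(self):
        # C(6,3) = 20 regroupings; |median diff| >= 9 for the two fully
        # sorted splits plus {1,2,10} vs {3,11,12} and its mirror -> 4/20
        res = perm.permutation_test_median_diff([1, 2, 3], [10, 11, 12])
        assert res.exact and res.n_permutations == 20
        assert res.p_value == pytest.approx(0.2)
        assert res.p_value == pytest.approx(
            enumeration_oracle([1, 2, 3], [10, 11, 12]))

    def test_matches_enumeration_oracle_randomly(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.integers(0, 10, size=na).astype(float).tolist()
            b = rng.integers(0, 10, size=nb).astype(float).tolist()
            res = perm.permutation_test_median_diff(a, b, n_permutations=10_000)
            assert res.exact
            assert res.p_value == pytest.approx(enumeration_oracle(a, b))

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.normal(size=4).tolist()
            b = rng.normal(size=5).tolist()
            pab = perm.permutation_test_median_diff(a, b).p_value
            pba = perm.permutation_test_median_diff(b, a).p_value
            assert pab == pytest.approx(pba)


class TestSampledMode:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12).tolist()
        b = rng.normal(size=9).tolist()
        r1 = perm.permutation_test_median_diff(a, b, 3000, seed=5)
        r2 = perm.permutation_test_median_diff(a, b, 3000, seed=5)
        assert not r1.exact
        assert r1.p_value == r2.p_value

    def test_add_one_estimator_floor(self):
        a = list(range(12))
        b = [x + 100 for x in range(9)]
        res = perm.permutation_test_median_diff(a, b, 2000, seed=1)
        assert res.p_value >= 1 / 2001

    def test_converges_to_exact(self):
        rng = np.random.default_rng(99)
        a = rng.normal(size=5).tolist()
        b = rng.normal(1.0, size=5).tolist()
        exact = perm.permutation_test_median_diff(a, b, 10_000)
        assert exact.exact
        # C(10,5) = 252, so a budget of 200 forces sampled mode
        assert comb(10, 5) == 252
        sampled = perm.permutation_test_median_diff(a, b, n_permutations=200, seed=3)
        assert not sampled.exact
        p = exact.p_value
        assert abs(sampled.p_value - p) <= 3 * np.sqrt(p * (1 - p) / 200) + 1 / 201

    def test_matches_scipy_reference(self):
        from scipy.stats import permutation_test as scipy_pt

        # equal group sizes: the permutation null is symmetric, so the
        # |stat|-based two-sided p coincides with scipy's doubled
        # one-sided definition
        rng = np.random.default_rng(4)
        a = rng.normal(size=7)
        b = rng.normal(0.8, size=7)

        def stat(x, y, axis):
            return np.median(x, axis=axis) - np.median(y, axis=axis)

        ours = perm.permutation_test_median_diff(a, b, n_permutations=100_000)
        ref = scipy_pt((a, b), stat, permutation_type="independent",
                       alternative="two-sided", n_resamples=np.inf)
        assert ours.exact
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestCompareGroups:
    def test_groups_split_and_summaries(self):
        values = {"a": 2, "b": 2, "c": 2, "x": 10, "y": 10, "z": 10}
        labels = dict.fromkeys("abc", "core") | dict.fromkeys("xyz", "accessory")
        res = perm.compare_groups(values, labels,
                                  group_order=("accessory", "core"))
        assert res.statistic_observed == 8.0
        assert res.exact and res.n_permutations == 20
        assert res.group_summaries["core"]["median"] == 2.0

    def test_all_equal_gives_p_one(self):
        values = dict.fromkeys("abcdef", 5.0)
        labels = dict.fromkeys("abc", "g1") | dict.fromkeys("def", "g2")
        assert perm.compare_groups(values, labels).p_value == 1.0

    def test_missing_label_errors(self):
        with pytest.raises(KeyError, match="'d'"):
            perm.compare_groups({"a": 1, "b": 2, "c": 3, "d": 4},
                                {"a": "x", "b": "x", "c": "y"})

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            perm.compare_groups({"a": 1, "b": 2, "c": 3},
                                {"a": "x", "b": "x", "c": "y"})


class TestKingdomPrevalence:
    def test_exact_small_case(self):
        records = [perm.KingdomPrevalenceRecord(s, v) for s, v in
                   [("s1", 0.9), ("s2", 0.95), ("s3", 0.1), ("s4", 0.15)]]
        labels = {"s1": "core", "s2": "core",
                  "s3": "accessory", "s4": "accessory"}
        res = perm.kingdom_prevalence_test(records, labels)
        assert res.exact and res.n_permutations == 6
        assert res.p_value == pytest.approx(enumeration_oracle(
            [0.1, 0.15], [0.9, 0.95]))

    def test_missing_record_lists_ids(self):
        records = [perm.KingdomPrevalenceRecord("s1", 0.9)]
        labels = {"s1": "core", "s2": "core", "s3": "accessory"}
        with pytest.raises(KeyError, match="s2"):
            perm.kingdom_prevalence_test(records, labels)

    def test_prevalence_range_validated(self):
        with pytest.raises(ValueError):
            perm.KingdomPrevalenceRecord("s", 1.2)
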