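"""Welch's t, Mann-Whitney U, and windowed cohort comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from krecout.stats import ComparisonSpec, compare_groups, mann_whitney, welch_t


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by brute-force relabelling."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [u_stat(set(c)) for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    cdf = sum(u <= u_obs for u in us) / total
    sf = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2 * min(cdf, sf))


class TestWelch:
    def test_worked_example_exact(self):
        res = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.statistic == pytest.approx(-1.0)
        assert res.degrees_of_freedom == pytest.approx(8.0)
        assert res.p_two_sided == pytest.approx(0.3466, abs=5e-4)

    def test_identical_samples_no_evidence(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_constant_equal_groups_convention(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_two_sided == 1.0

    def test_location_shift_invariance(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        a = welch_t(x, y)
        b = welch_t(x + 100, y + 100)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.degrees_of_freedom == pytest.approx(b.degrees_of_freedom)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_symmetric_under_group_swap(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 3, 18)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_matches_scipy_reference(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(2, 30))
            y = rng.normal(0.3, 2, rng.integers(2, 30))
            ours = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_values_center_and_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2
        assert res.p_two_sided == 1.0

    def test_u_statistics_sum_to_n1_n2(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(1, 15))
            y = rng.normal(0.5, 1, rng.integers(1, 15))
            ua = mann_whitney(x, y).statistic
            ub = mann_whitney(y, x).statistic
            assert ua + ub == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_for_all_small_sizes(self, rng):
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                x, y = vals[:n1], vals[n1:]
                res = mann_whitney(x, y)
                u_ref, p_ref = mw_enumeration_oracle(x, y)
                assert res.statistic == pytest.approx(u_ref)
                assert res.p_two_sided == pytest.approx(p_ref, rel=1e-12)

    def test_exact_and_normal_approximation_agree_at_moderate_n(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.4, 1, 15)
        exact = mann_whitney(x, y, exact_threshold=20).p_two_sided
        approx = mann_whitney(x, y, exact_threshold=1).p_two_sided
        assert abs(exact - approx) < 0.02

    def test_matches_scipy_reference(self, rng):
        x, y = rng.normal(0, 1, 25), rng.normal(0.5, 1, 30)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestCompareGroups:
    def _frame(self):
        rng = np.random.default_rng(0)
        n = 60
        return pd.DataFrame(
            {
                "cohort": ["CWC"] * n + ["ART-96W"] * n,
                "age_years": np.tile(np.linspace(0.1, 1.9, n), 2),
                "theta": np.concatenate(
                    [rng.lognormal(20, 0.4, n), rng.lognormal(20.7, 0.4, n)]
                ),
            }
        )

    def test_windowed_welch_detects_shift(self):
        spec = ComparisonSpec("ART-96W", "CWC", (0.0, 2.0))
        res = compare_groups(self._frame(), spec)
        assert res.n_a == res.n_b == 60
        assert res.p_two_sided < 0.01
        assert res.mean_a > res.mean_b  # infected above uninfected

    def test_window_filter_counts(self):
        spec = ComparisonSpec("ART-96W", "CWC", (0.0, 1.0), test="mann_whitney")
        res = compare_groups(self._frame(), spec)
        df = self._frame()
        expect = ((df.age_years < 1.0) & (df.cohort == "CWC")).sum()
        assert res.n_b == expect

    def test_empty_group_after_filter_errors_with_name(self):
        spec = ComparisonSpec("ART-Def", "CWC", (0.0, 2.0))
        with pytest.raises(ValueError, match="ART-Def"):
            compare_groups(self._frame(), spec)

    def test_window_excluding_everyone_errors(self):
        spec = ComparisonSpec("ART-96W", "CWC", (10.0, 12.0))
        with pytest.raises(ValueError):
            compare_groups(self._frame(), spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ComparisonSpec("A", "A", (0.0, 2.0))
        with pytest.raises(ValueError):
            ComparisonSpec("A", "B", (2.0, 0.0))
        with pytest.raises(ValueError):
            ComparisonSpec("A", "B", (0.0, 2.0), test="anova")
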