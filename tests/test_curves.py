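"""Reference tables, quantile-regression curves, bands, duplicate checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krecout import curves
from krecout.curves import (
    HEALTHY_BANDS,
    HIV_ART_BANDS,
    AgeBandScheme,
    age_knots,
    check_loss,
    duplicate_sensitivity,
    fit_median_curve,
    natural_spline_basis,
    reference_table,
    simultaneous_band,
)


def quantile_oracle(values, q):
    """Sort-and-interpolate (type 7) quantile, written independently."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def one_band_frame(values, band=HEALTHY_BANDS):
    n = len(values)
    return pd.DataFrame(
        {"age_days": np.full(n, 30), "m": values}  # all inside 0-3 months
    )


class TestReferenceTable:
    def test_known_quantiles_of_1_to_100(self):
        tab = reference_table(one_band_frame(np.arange(1, 101)), HEALTHY_BANDS, ["m"])
        row = tab[(tab.band == "0-3 mo") & (tab.measure == "m")].iloc[0]
        assert row["n"] == 100
        assert row["median"] == pytest.approx(50.5)
        assert (row["iqr_lo"], row["iqr_hi"]) == (pytest.approx(25.75), pytest.approx(75.25))
        assert (row["p5"], row["p95"]) == (pytest.approx(5.95), pytest.approx(95.05))

    def test_single_value_band_collapses_all_statistics(self):
        tab = reference_table(one_band_frame([7.0]), HEALTHY_BANDS, ["m"])
        row = tab.iloc[0]
        assert all(row[k] == 7.0 for k in ("median", "iqr_lo", "iqr_hi", "p5", "p95"))

    def test_band_counts_partition_cohort(self, healthy_cohort_default_noise):
        ann, _ = healthy_cohort_default_noise
        tab = reference_table(ann, HEALTHY_BANDS, ["theta"])
        assert tab["n"].sum() == len(ann)

    def test_empty_bands_reported_with_zero_n(self):
        tab = reference_table(one_band_frame([1.0, 2.0]), HEALTHY_BANDS, ["m"])
        empty = tab[tab.band != "0-3 mo"]
        assert (empty["n"] == 0).all()
        assert empty["median"].isna().all()

    def test_row_order_permutation_invariance(self, rng):
        df = pd.DataFrame(
            {"age_days": rng.integers(0, 4380, 200), "m": rng.lognormal(0, 1, 200)}
        )
        a = reference_table(df, HEALTHY_BANDS, ["m"])
        b = reference_table(df.sample(frac=1, random_state=1), HEALTHY_BANDS, ["m"])
        pd.testing.assert_frame_equal(a, b)

    def test_centile_ordering_invariant(self, healthy_cohort_default_noise):
        ann, _ = healthy_cohort_default_noise
        tab = reference_table(
            ann, HEALTHY_BANDS, ["theta", "krec_per_pbmc", "krec_per_million_naive_b"]
        )
        filled = tab.dropna()
        assert (filled.p5 <= filled.iqr_lo).all()
        assert (filled.iqr_lo <= filled["median"]).all()
        assert (filled["median"] <= filled.iqr_hi).all()
        assert (filled.iqr_hi <= filled.p95).all()

    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=60,
        ),
        q=st.sampled_from([0.05, 0.25, 0.5, 0.75, 0.95]),
    )
    @settings(max_examples=1000, deadline=None)
    def test_quantiles_match_sort_interpolate_oracle(self, values, q):
        assert np.quantile(np.array(values), q) == pytest.approx(
            quantile_oracle(values, q), rel=1e-9, abs=1e-9
        )


class TestBanding:
    def test_bands_exhaustive_and_exclusive(self):
        days = np.arange(0, HEALTHY_BANDS.edges_days[-1] + 1)
        labels = HEALTHY_BANDS.assign(days)
        assert not pd.isna(pd.Series(labels)).any()
        # strictly one band per age by construction of searchsorted
        assert set(labels) == set(HEALTHY_BANDS.labels)

    def test_half_open_edges_and_closed_top(self):
        e = HEALTHY_BANDS.edges_days
        assert HEALTHY_BANDS.assign([e[1] - 1])[0] == "0-3 mo"
        assert HEALTHY_BANDS.assign([e[1]])[0] == "3-6 mo"
        assert HEALTHY_BANDS.assign([e[-1]])[0] == "6-12 y"

    def test_out_of_range_is_none(self):
        assert HIV_ART_BANDS.assign([HIV_ART_BANDS.edges_days[-1] + 1])[0] is None

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            AgeBandScheme((0, 10, 5), ("a", "b"))
        with pytest.raises(ValueError):
            AgeBandScheme((0, 10), ("a", "b"))


class TestMedianCurveFit:
    def test_interpolation_identity_for_in_span_data(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 120))
        knots = age_knots(ages)
        beta = np.array([8.0, -0.5, 0.3, 0.2, -0.1])[: len(knots) + 1]
        vals = 10 ** (natural_spline_basis(np.log10(ages), knots) @ beta)
        fit = fit_median_curve(ages, vals, knots=knots)
        resid = np.log10(vals) - np.log10(fit(ages))
        assert check_loss(resid) < 1e-7
        assert np.allclose(fit(ages), vals, rtol=1e-6)

    def test_constant_data_gives_flat_curve(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 80))
        fit = fit_median_curve(ages, np.full(80, 42.0))
        assert np.allclose(fit.fitted, 42.0, rtol=1e-8)

    def test_beats_any_constant_fit(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 150))
        vals = np.exp(rng.normal(np.log(100) - np.log1p(ages), 0.5))
        fit = fit_median_curve(ages, vals)
        fit_loss = check_loss(np.log10(vals) - np.log10(fit(ages)))
        for const in np.quantile(np.log10(vals), [0.3, 0.5, 0.7]):
            assert fit_loss <= check_loss(np.log10(vals) - const) + 1e-9

    def test_median_regression_unbiased_under_symmetric_noise(self, rng):
        # Monte-Carlo: mean fitted curve within 5% of truth at grid ages
        grid = np.array([0.25, 0.5, 1, 2, 4, 8])
        knots = np.log10([0.04, 0.3, 3.2, 6.5, 12.0])
        beta_true = np.array([8.5, -0.4, 0.25, 0.15, -0.05])
        truth = 10 ** (natural_spline_basis(np.log10(grid), knots) @ beta_true)
        fits = []
        for _ in range(30):
            ages = np.exp(rng.uniform(np.log(0.04), np.log(12), 200))
            mu = natural_spline_basis(np.log10(ages), knots) @ beta_true
            vals = 10 ** (mu + rng.normal(0, 0.3, 200))
            fits.append(fit_median_curve(ages, vals, knots=knots, grid=grid).fitted)
        assert np.allclose(np.mean(fits, axis=0), truth, rtol=0.05)

    def test_lp_solution_matches_statsmodels_quantreg(self, rng):
        # independent IRLS implementation of the same check-loss problem
        import statsmodels.api as sm

        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 250))
        vals = np.exp(rng.normal(20 - 0.5 * np.log1p(ages), 0.4))
        knots = age_knots(ages)
        fit = fit_median_curve(ages, vals, knots=knots)
        basis = natural_spline_basis(np.log10(ages), knots)
        ref = sm.QuantReg(np.log10(vals), basis).fit(q=0.5)
        ours = basis @ fit.coefficients
        assert np.allclose(ours, ref.fittedvalues, atol=1e-4)
        loss_ours = check_loss(np.log10(vals) - ours)
        loss_ref = check_loss(np.log10(vals) - ref.fittedvalues)
        assert loss_ours <= loss_ref + 1e-8  # LP attains the optimum

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="all ages equal"):
            fit_median_curve(np.full(100, 1.0), np.arange(1, 101))
        with pytest.raises(ValueError, match="> 0"):
            fit_median_curve(np.linspace(0.1, 10, 100), np.zeros(100))
        with pytest.raises(ValueError, match="points"):
            fit_median_curve(np.linspace(0.1, 10, 20), np.ones(20) + np.arange(20))


class TestSimultaneousBand:
    def test_band_contains_point_estimate_and_is_deterministic(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 150))
        vals = np.exp(rng.normal(20 - np.log1p(ages), 0.4))
        fit = fit_median_curve(ages, vals)
        b1 = simultaneous_band(fit, ages, vals, n_boot=120, seed=7)
        b2 = simultaneous_band(fit, ages, vals, n_boot=120, seed=7)
        assert np.all(b1.band_lo <= b1.fitted) and np.all(b1.fitted <= b1.band_hi)
        assert np.array_equal(b1.band_lo, b2.band_lo)
        b3 = simultaneous_band(fit, ages, vals, n_boot=120, seed=8)
        assert not np.array_equal(b1.band_lo, b3.band_lo)

    def test_band_width_collapses_for_noiseless_in_span_data(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 120))
        knots = age_knots(ages)
        beta = np.array([8.0, -0.5, 0.3, 0.2, -0.1])[: len(knots) + 1]
        vals = 10 ** (natural_spline_basis(np.log10(ages), knots) @ beta)
        fit = fit_median_curve(ages, vals, knots=knots)
        band = simultaneous_band(fit, ages, vals, n_boot=120, seed=0)
        assert np.max((band.band_hi - band.band_lo) / band.fitted) < 1e-5

    def test_small_n_boot_warns_but_proceeds(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(12), 120))
        vals = np.exp(rng.normal(10, 0.3, 120))
        fit = fit_median_curve(ages, vals)
        with pytest.warns(UserWarning, match="n_boot"):
            band = simultaneous_band(fit, ages, vals, n_boot=50, seed=0)
        assert band.band_lo is not None


class TestDuplicateSensitivity:
    def test_no_duplicates_gap_is_zero(self, rng):
        ages = np.exp(rng.uniform(np.log(0.05), np.log(8), 100))
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(100)],
                "age_years": ages,
                "theta": np.exp(rng.normal(20, 0.4, 100)),
            }
        )
        _, _, gap = duplicate_sensitivity(df, "theta", seed=0)
        assert gap == 0.0

    def test_same_seed_same_subsample(self, rng):
        ages = np.exp(rng.uniform(np.log(0.15), np.log(8), 140))
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i % 80}" for i in range(140)],
                "age_years": ages,
                "theta": np.exp(rng.normal(20, 0.3, 140)),
            }
        )
        _, d1, g1 = duplicate_sensitivity(df, "theta", seed=5)
        _, d2, g2 = duplicate_sensitivity(df, "theta", seed=5)
        assert g1 == g2
        assert np.array_equal(d1.fitted, d2.fitted)
        assert g1 > 0  # duplicates present, subsample differs from full fit
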