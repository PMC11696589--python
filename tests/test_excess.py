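"""Seasonal Poisson baseline, bootstrap prediction intervals, excess tables."""

import numpy as np
import pandas as pd
import pytest

from fluexcess._glm import PoissonFitError, fit_poisson
from fluexcess.datamodel import MonthlyDeathSeries, ValidationError
from fluexcess.excess import (
    compute_excess,
    fit_baseline,
    harmonic_design,
    pool_series,
    predict_expected,
    run_excess_panel,
)
from fluexcess.synthetic import SeriesScenario, simulate_monthly_series


def _constant_series(k=5, n=36, pop=1.0):
    t = np.arange(n)
    return MonthlyDeathSeries("toy", 1885 + t // 12, t % 12 + 1,
                              np.full(n, k), np.full(n, pop))


class TestFitBaseline:
    def test_constant_counts_give_exact_intercept(self):
        m = fit_baseline(_constant_series(k=5), ((1885, 1), (1887, 12)))
        assert np.exp(m.coefficients[0]) == pytest.approx(5.0, rel=1e-8)
        assert m.coefficients[1] == pytest.approx(0.0, abs=1e-8)
        assert m.coefficients[2] == pytest.approx(0.0, abs=1e-8)

    def test_flat_scenario_recovers_rate_within_2se(self, flat_series):
        m = fit_baseline(flat_series)
        se = np.sqrt(np.diag(m.covariance))
        assert abs(np.exp(m.coefficients[0]) - 2e-3) < \
            2 * se[0] * np.exp(m.coefficients[0])
        assert abs(m.coefficients[1]) < 2 * se[1]
        assert abs(m.coefficients[2]) < 2 * se[2]

    def test_mle_beats_likelihood_grid(self):
        """Grid-search oracle: no point on a 21^3 grid around the optimum
        has higher log-likelihood than the fitted coefficients."""
        sc = SeriesScenario(n_years=3, seed=77, shock_months=frozenset())
        s = simulate_monthly_series(sc)
        m = fit_baseline(s, ((1885, 1), (1887, 12)))
        X = harmonic_design(s.months)
        off = np.log(s.population)
        y = s.deaths

        def ll(beta):
            eta = off + X @ beta
            return y @ eta - np.exp(eta).sum()

        best = ll(m.coefficients)
        grid = np.linspace(-0.05, 0.05, 21)
        for d0 in grid:
            for d1 in grid:
                for d2 in grid:
                    assert ll(m.coefficients + [d0, d1, d2]) <= best + 1e-9

    def test_agrees_with_statsmodels_glm(self, default_series):
        import statsmodels.api as sm

        model = fit_baseline(default_series)
        sub = default_series.window(*model.fit_window)
        X = harmonic_design(sub.months)
        glm = sm.GLM(sub.deaths, X, family=sm.families.Poisson(),
                     offset=np.log(sub.population)).fit()
        np.testing.assert_allclose(model.coefficients, glm.params, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(model.covariance)),
                                   glm.bse, rtol=1e-6)

    def test_all_zero_deaths_is_degenerate(self):
        s = _constant_series(k=0)
        with pytest.raises(PoissonFitError, match="zero"):
            fit_baseline(s, ((1885, 1), (1887, 12)))

    def test_short_window_rejected(self):
        with pytest.raises(ValidationError, match="24"):
            fit_baseline(_constant_series(n=36), ((1885, 1), (1886, 9)))


class TestPredictExpected:
    def test_pi_width_matches_poisson_normal_approx(self):
        sc = SeriesScenario(seasonal_amplitude=0.0, shock_months=frozenset(),
                            population_start=4e6, population_growth=0.0,
                            n_years=6, seed=5)
        s = simulate_monthly_series(sc)
        m = fit_baseline(s, ((1885, 1), (1889, 12)))
        tab = predict_expected(m, s, ((1890, 1), (1890, 12)),
                               n_boot=2000, seed=1)
        lam = tab["expected"].to_numpy()
        width = (tab["pi_high"] - tab["pi_low"]).to_numpy()
        # bootstrap PI also carries estimation noise, so allow 15% head-room
        np.testing.assert_allclose(width, 2 * 1.96 * np.sqrt(lam), rtol=0.15)
        assert np.all(tab["pi_low"] <= lam) and np.all(lam <= tab["pi_high"])

    def test_seeded_bootstrap_is_bit_identical(self, default_series):
        m = fit_baseline(default_series)
        a = predict_expected(m, default_series, n_boot=200, seed=9)
        b = predict_expected(m, default_series, n_boot=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_boot_warns(self, default_series):
        m = fit_baseline(default_series)
        with pytest.warns(UserWarning, match="n_boot"):
            predict_expected(m, default_series, n_boot=50, seed=1)


class TestComputeExcess:
    def test_hand_arithmetic(self):
        tab = pd.DataFrame({"unit": "u", "year": [1890], "month": [1],
                            "observed": [150], "expected": [100.0],
                            "pi_low": [80.0], "pi_high": [120.0]})
        out = compute_excess(tab)
        r = out.iloc[0]
        assert r.excess_abs == pytest.approx(50.0)
        assert r.excess_pct == pytest.approx(50.0)
        assert r.excess_pct_low == pytest.approx(30.0)
        assert r.excess_pct_high == pytest.approx(70.0)
        assert r.significant == "excess"

    def test_observed_equal_expected_is_null(self):
        tab = pd.DataFrame({"unit": "u", "year": [1890], "month": [1],
                            "observed": [100], "expected": [100.0],
                            "pi_low": [80.0], "pi_high": [120.0]})
        r = compute_excess(tab).iloc[0]
        assert r.excess_abs == 0 and r.excess_pct == 0
        assert r.significant == "none"

    def test_deficit_flag_and_sign_consistency(self, default_series):
        m = fit_baseline(default_series)
        out = compute_excess(predict_expected(m, default_series,
                                              n_boot=300, seed=3))
        assert np.all(np.sign(out.excess_abs) == np.sign(out.excess_pct))
        assert np.all(out.excess_pct_low <= out.excess_pct_high)
        flagged = out[out.significant == "deficit"]
        assert np.all(flagged.observed < flagged.pi_low)

    def test_non_positive_expected_rejected(self):
        tab = pd.DataFrame({"unit": "u", "year": [1890], "month": [1],
                            "observed": [1], "expected": [0.0],
                            "pi_low": [0.0], "pi_high": [1.0]})
        with pytest.raises(ValidationError):
            compute_excess(tab)


class TestPanel:
    def test_identical_cities_pool_to_same_excess(self):
        units = [simulate_monthly_series(
            SeriesScenario(seed=100 + k, unit_id=f"c{k}")) for k in range(3)]
        tables, summary = run_excess_panel(units, n_boot=150, seed=4)
        jan = {u: float(t[(t.year == 1890) & (t.month == 1)].excess_pct.iloc[0])
               for u, t in tables.items()}
        pooled = jan.pop("all_cities")
        # same scenario in every city: pooled estimate near the city mean,
        # well within Poisson noise of the injected 58.9%
        assert pooled == pytest.approx(np.mean(list(jan.values())), abs=15)
        assert 30 < pooled < 90
        assert set(summary.month) <= {12, 1, 2}

    def test_pooled_excess_between_shocked_and_unshocked(self):
        shocked = simulate_monthly_series(
            SeriesScenario(seed=1, unit_id="hit"))
        calm = [simulate_monthly_series(
            SeriesScenario(seed=2 + k, unit_id=f"calm{k}",
                           shock_months=frozenset())) for k in range(2)]
        tables, _ = run_excess_panel([shocked] + calm, n_boot=150, seed=8)
        jan = {u: float(t[(t.year == 1890) & (t.month == 1)].excess_pct.iloc[0])
               for u, t in tables.items()}
        lo = min(jan["calm0"], jan["calm1"])
        hi = jan["hit"]
        assert lo < jan["all_cities"] < hi

    def test_short_unit_skipped(self, caplog):
        good = simulate_monthly_series(SeriesScenario(seed=1, unit_id="good"))
        short = _constant_series(n=20)
        tables, _ = run_excess_panel([good, short], n_boot=120, seed=2,
                                     fit_window=((1885, 1), (1889, 11)),
                                     pooled_label=None)
        assert "good" in tables and "toy" not in tables

    def test_additivity_of_absolute_excess_at_flat_rate(self):
        units = [simulate_monthly_series(
            SeriesScenario(seed=50 + k, unit_id=f"u{k}",
                           seasonal_amplitude=0.0)) for k in range(2)]
        tables, _ = run_excess_panel(units, n_boot=120, seed=6)
        jan = {u: float(t[(t.year == 1890) & (t.month == 1)].excess_abs.iloc[0])
               for u, t in tables.items()}
        # pooled fit on summed counts vs sum of separate fits
        assert jan["all_cities"] == pytest.approx(jan["u0"] + jan["u1"],
                                                  abs=3.0)


def test_fit_poisson_handles_offset_scaling():
    """Doubling the population offset halves the fitted rate exactly."""
    rng = np.random.default_rng(3)
    X = np.ones((40, 1))
    y = rng.poisson(50, 40).astype(float)
    b1, *_ = fit_poisson(X, y, np.log(np.full(40, 1e4)))
    b2, *_ = fit_poisson(X, y, np.log(np.full(40, 2e4)))
    assert b1[0] - b2[0] == pytest.approx(np.log(2), abs=1e-8)
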