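"""Repeated-simulation studies used to validate the estimators.

These are the package's own calibration experiments: prediction-interval
coverage, shock (excess) recovery, robust-slope CI coverage and the
cross-protection null — each a pure function of its parameters and a
base seed, returning plain dicts of summary numbers.
"""

from __future__ import annotations

import numpy as np

from .excess import compute_excess, fit_baseline, predict_expected
from .regression import cross_protection, robust_fit
from .synthetic import DistrictScenario, SeriesScenario, simulate_district_table, simulate_monthly_series

__all__ = [
    "pi_coverage_study",
    "shock_recovery_study",
    "slope_coverage_study",
    "cross_protection_null_study",
]

_P = 2 ** 31 - 1


def _sub_seed(seed: int, k: int) -> int:
    return (seed + 7919 * (k + 1)) % _P


def pi_coverage_study(
    n_rep: int = 500,
    n_boot: int = 500,
    seed: int = 1890,
    amplitude: float = 0.3,
    baseline_rate: float = 2e-3,
    population: float = 1e5,
) -> dict:
    """Empirical coverage of the 95% bootstrap prediction intervals.

    Each replicate simulates a 72-month seasonal Poisson series with no
    shock, fits the baseline on months 1–60 and computes bootstrap PIs
    for months 61–72; coverage is the fraction of held-out observed
    counts inside their interval.
    """
    inside = 0
    total = 0
    for k in range(n_rep):
        sc = SeriesScenario(
            n_years=6,
            seasonal_amplitude=amplitude,
            baseline_rate=baseline_rate,
            population_start=population,
            population_growth=0.0,
            shock_months=frozenset(),
            seed=_sub_seed(seed, k),
        )
        series = simulate_monthly_series(sc)
        model = fit_baseline(series, ((1885, 1), (1889, 12)))
        tab = predict_expected(model, series, ((1890, 1), (1890, 12)),
                               n_boot=n_boot, seed=_sub_seed(seed, n_rep + k))
        inside += int(((tab["observed"] >= tab["pi_low"])
                       & (tab["observed"] <= tab["pi_high"])).sum())
        total += len(tab)
    return {"coverage_pct": 100.0 * inside / total,
            "n_rep": n_rep, "n_months": total}


def shock_recovery_study(
    multiplier: float = 1.589,
    n_rep: int = 200,
    seed: int = 1890,
    n_boot: int = 100,
    n_harmonics: int = 3,
    population: float = 1e5,
    baseline_rate: float = 2e-3,
) -> dict:
    """Mean estimated relative excess under a known multiplicative shock.

    A shock of ``multiplier`` is injected into January 1890 (a
    prediction-window month); the full pipeline — baseline fit,
    bootstrap prediction, excess computation — is run per replicate and
    the estimated January-1890 ``excess_pct`` averaged. Three harmonics
    are used so the baseline family contains the generator's seasonal
    shape (see docs: one log-scale harmonic only approximates the
    linear-in-sine seasonal factor).
    """
    vals = np.empty(n_rep)
    for k in range(n_rep):
        sc = SeriesScenario(
            shock_months=frozenset({(1890, 1)}),
            shock_multiplier=multiplier,
            population_start=population,
            baseline_rate=baseline_rate,
            seed=_sub_seed(seed, k),
        )
        series = simulate_monthly_series(sc)
        model = fit_baseline(series, n_harmonics=n_harmonics)
        tab = compute_excess(predict_expected(
            model, series, ((1890, 1), (1890, 1)),
            n_boot=n_boot, seed=_sub_seed(seed, n_rep + k)))
        vals[k] = float(tab["excess_pct"].iloc[0])
    return {
        "mean_excess_pct": float(vals.mean()),
        "mc_se": float(vals.std(ddof=1) / np.sqrt(n_rep)),
        "injected_pct": 100.0 * (multiplier - 1.0),
        "n_rep": n_rep,
    }


def slope_coverage_study(
    n_rep: int = 200,
    seed: int = 1890,
    predictors: tuple[str, ...] = ("altitude_m", "density"),
) -> dict:
    """95% CI coverage of known generator slopes in robust regressions."""
    base = DistrictScenario()
    true = {p: base.covariate_effects[p] for p in predictors}
    covered = {p: 0 for p in predictors}
    for k in range(n_rep):
        records, _ = simulate_district_table(
            DistrictScenario(seed=_sub_seed(seed, k)))
        y = np.array([r.flu_mortality_by_year["1889/90"] for r in records])
        for p in predictors:
            x = np.array([getattr(r, p) for r in records])
            fit = robust_fit(y, x, predictor_label=p)
            covered[p] += fit.ci_low <= true[p] <= fit.ci_high
    return {
        "coverage_pct": {p: 100.0 * covered[p] / n_rep for p in predictors},
        "true_slopes": true,
        "n_rep": n_rep,
    }


def cross_protection_null_study(n_rep: int = 200, seed: int = 1890) -> dict:
    """CI coverage of zero when the later wave is independent of the first."""
    covered = 0
    for k in range(n_rep):
        records, _ = simulate_district_table(
            DistrictScenario(seed=_sub_seed(seed, k),
                             later_year_coupling=0.0))
        fit, _ = cross_protection(records, stratify_urban=False)
        covered += fit.ci_low <= 0.0 <= fit.ci_high
    return {"coverage_pct": 100.0 * covered / n_rep, "n_rep": n_rep}
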