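"""Seasonal Poisson baseline and bootstrap excess-mortality estimation.

The expected number of deaths in calendar month m of a unit with
population P_t is modelled on pre-pandemic years as

    log E[D_t] = log P_t + b0 + sum_j [ b_sj sin(2*pi*j*m/12) + b_cj cos(2*pi*j*m/12) ]

(one harmonic pair, j = 1, by default). The model is fitted by maximum
likelihood on a pre-pandemic window (60 months by default) and projected
forward "as if no epidemic"; 95% prediction intervals for the observed
counts come from a parametric bootstrap: resample counts on the fit
window from Poisson(mu_hat), refit, predict mu*, and draw y* ~
Poisson(mu*). Excess mortality is observed minus expected, also
expressed as a percentage of expected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import PoissonFitError, fit_poisson, fit_poisson_batch, poisson_loglik
from .datamodel import MonthlyDeathSeries, ValidationError

__all__ = [
    "BaselineModel",
    "fit_baseline",
    "predict_expected",
    "compute_excess",
    "run_excess_panel",
    "pool_series",
    "winter_summary",
    "harmonic_design",
    "EXCESS_COLUMNS",
]

logger = logging.getLogger(__name__)

EXCESS_COLUMNS = [
    "unit", "year", "month", "observed", "expected", "pi_low", "pi_high",
    "excess_abs", "excess_pct", "excess_pct_low", "excess_pct_high",
    "significant",
]

#: Default epidemic onset: December 1889. The default fit window is the
#: 60 months ending the month before.
DEFAULT_ONSET = (1889, 12)


def harmonic_design(months: np.ndarray, n_harmonics: int = 1) -> np.ndarray:
    """Design matrix [1, sin(2*pi*j*m/12), cos(2*pi*j*m/12)]_{j=1..k}."""
    m = np.asarray(months, dtype=float)
    cols = [np.ones_like(m)]
    for j in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * j * m / 12.0
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


@dataclass
class BaselineModel:
    """Fitted pre-pandemic baseline for one unit.

    ``coefficients`` are on the log-rate scale: intercept, then
    (sine, cosine) per harmonic. ``covariance`` is the inverse observed
    information at the optimum.
    """

    unit_id: str
    coefficients: np.ndarray
    covariance: np.ndarray
    fit_window: tuple[tuple[int, int], tuple[int, int]]
    log_likelihood: float
    converged: bool
    n_iter: int
    n_harmonics: int = 1
    # fit-window internals kept for the parametric bootstrap
    _X_fit: np.ndarray = field(default=None, repr=False)
    _offset_fit: np.ndarray = field(default=None, repr=False)
    _y_fit: np.ndarray = field(default=None, repr=False)

    @property
    def fitted_means(self) -> np.ndarray:
        return np.exp(self._offset_fit + self._X_fit @ self.coefficients)

    def expected(self, series: MonthlyDeathSeries,
                 window: tuple[tuple[int, int], tuple[int, int]] | None = None
                 ) -> pd.DataFrame:
        """Point expectation E[deaths] for months of ``series``."""
        sub = series if window is None else series.window(*window)
        X = harmonic_design(sub.months, self.n_harmonics)
        mu = np.exp(np.log(sub.population) + X @ self.coefficients)
        return pd.DataFrame(
            {"unit": sub.unit_id, "year": sub.years, "month": sub.months,
             "observed": sub.deaths, "expected": mu}
        )


def _default_fit_window(series: MonthlyDeathSeries,
                        onset: tuple[int, int] = DEFAULT_ONSET,
                        n_months: int = 60):
    """60 months ending immediately before the epidemic onset month.

    Falls back to the first 60 months when the series does not reach the
    onset (synthetic series with arbitrary calendars).
    """
    idx = series.month_index
    onset_idx = onset[0] * 12 + onset[1] - 1
    if idx[0] < onset_idx <= idx[-1]:
        end = onset_idx - 1
        start = max(int(idx[0]), end - n_months + 1)
    else:
        start = int(idx[0])
        end = min(int(idx[-1]), start + n_months - 1)
    return ((start // 12, start % 12 + 1), (end // 12, end % 12 + 1))


def fit_baseline(
    series: MonthlyDeathSeries,
    fit_window: tuple[tuple[int, int], tuple[int, int]] | None = None,
    n_harmonics: int = 1,
) -> BaselineModel:
    """Fit the seasonal Poisson baseline on a pre-pandemic window.

    ``fit_window`` is ((year, month), (year, month)) inclusive; by
    default the 60 months preceding December 1889 (or the first 60
    months of a series that does not span that date). At least 24 months
    are required.
    """
    if fit_window is None:
        fit_window = _default_fit_window(series)
    sub = series.window(*fit_window)
    if len(sub) < 24:
        raise ValidationError(
            f"{series.unit_id}: fit window has {len(sub)} months, need >= 24"
        )
    X = harmonic_design(sub.months, n_harmonics)
    offset = np.log(sub.population)
    try:
        beta, cov, ll, n_iter = fit_poisson(X, sub.deaths, offset)
    except PoissonFitError as exc:
        raise PoissonFitError(
            f"{series.unit_id}: baseline fit failed: {exc}", exc.trace
        ) from exc
    return BaselineModel(
        unit_id=series.unit_id,
        coefficients=beta,
        covariance=cov,
        fit_window=fit_window,
        log_likelihood=ll,
        converged=True,
        n_iter=n_iter,
        n_harmonics=n_harmonics,
        _X_fit=X,
        _offset_fit=offset,
        _y_fit=sub.deaths.astype(float),
    )


def predict_expected(
    model: BaselineModel,
    series: MonthlyDeathSeries,
    predict_window: tuple[tuple[int, int], tuple[int, int]] | None = None,
    n_boot: int = 1000,
    seed: int = 1890,
    level: float = 0.95,
) -> pd.DataFrame:
    """Expected deaths with bootstrap prediction intervals.

    For each bootstrap replicate, counts on the fit window are resampled
    from Poisson(mu_hat), the model refitted, means mu* predicted on the
    prediction window, and a future count y* ~ Poisson(mu*) drawn. The
    PI bounds are the (2.5, 97.5)% empirical quantiles of the y*.
    Deterministic for a fixed ``seed``.
    """
    if not model.converged:
        raise ValueError(f"{model.unit_id}: model did not converge")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} < 100: prediction-interval quantiles will be "
            "noisy", stacklevel=2,
        )
    if predict_window is None:
        end_idx = model.fit_window[1][0] * 12 + model.fit_window[1][1] - 1
        idx = series.month_index
        if idx[-1] <= end_idx:
            raise ValidationError(
                f"{series.unit_id}: nothing to predict after the fit window"
            )
        start = end_idx + 1
        predict_window = ((start // 12, start % 12 + 1),
                          (int(series.years[-1]), int(series.months[-1])))
    sub = series.window(*predict_window)
    tab = model.expected(sub)

    rng = np.random.default_rng(seed)
    mu_fit = model.fitted_means
    Xp = harmonic_design(sub.months, model.n_harmonics)
    off_p = np.log(sub.population)

    Ystar = rng.poisson(mu_fit, size=(n_boot, len(mu_fit)))
    betas, ok = fit_poisson_batch(
        model._X_fit, Ystar, model._offset_fit, start=model.coefficients
    )
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("%s: %d/%d bootstrap refits dropped",
                       model.unit_id, n_failed, n_boot)
        if n_failed > 0.05 * n_boot:
            raise PoissonFitError(
                f"{model.unit_id}: {n_failed}/{n_boot} bootstrap refits failed"
            )
    mu_star = np.exp(off_p[None, :] + betas[ok] @ Xp.T)     # (B_ok, n_pred)
    y_star = rng.poisson(mu_star)
    alpha = (1.0 - level) / 2.0
    tab["pi_low"] = np.quantile(y_star, alpha, axis=0)
    tab["pi_high"] = np.quantile(y_star, 1.0 - alpha, axis=0)
    return tab


def compute_excess(expected_table: pd.DataFrame,
                   observed: MonthlyDeathSeries | None = None) -> pd.DataFrame:
    """Fill absolute/relative excess and significance flags.

    ``expected_table`` needs columns year, month, expected, pi_low,
    pi_high (as produced by :func:`predict_expected`); observed counts
    are taken from the table itself unless ``observed`` is given, in
    which case months are aligned on (year, month). A month is flagged
    ``excess`` when observed exceeds the upper PI bound, ``deficit``
    when below the lower bound.
    """
    tab = expected_table.copy()
    if observed is not None:
        obs = observed.to_frame()[["year", "month", "deaths"]]
        tab = tab.drop(columns=[c for c in ("observed",) if c in tab], errors="ignore")
        merged = tab.merge(obs, on=["year", "month"], how="left")
        if merged["deaths"].isna().any():
            r = merged[merged["deaths"].isna()].iloc[0]
            raise ValidationError(
                f"no observed deaths for {int(r.year)}-{int(r.month):02d}"
            )
        tab = merged.rename(columns={"deaths": "observed"})
    if (tab["expected"] <= 0).any():
        raise ValidationError("non-positive expected deaths")
    exp = tab["expected"].to_numpy(dtype=float)
    obs_v = tab["observed"].to_numpy(dtype=float)
    tab["excess_abs"] = obs_v - exp
    tab["excess_pct"] = 100.0 * (obs_v - exp) / exp
    lo = 100.0 * (obs_v - tab["pi_high"].to_numpy()) / exp
    hi = 100.0 * (obs_v - tab["pi_low"].to_numpy()) / exp
    tab["excess_pct_low"] = np.minimum(lo, hi)
    tab["excess_pct_high"] = np.maximum(lo, hi)
    tab["significant"] = np.select(
        [obs_v > tab["pi_high"], obs_v < tab["pi_low"]],
        ["excess", "deficit"],
        default="none",
    )
    cols = [c for c in EXCESS_COLUMNS if c in tab.columns]
    return tab[cols + [c for c in tab.columns if c not in cols]]


def pool_series(units: list[MonthlyDeathSeries],
                label: str = "all_cities") -> MonthlyDeathSeries:
    """Sum death counts and populations month-by-month across units."""
    frames = [u.to_frame() for u in units]
    base = frames[0][["year", "month"]]
    for f in frames[1:]:
        if not base.equals(f[["year", "month"]]):
            raise ValidationError("units cover different months; cannot pool")
    deaths = sum(f["deaths"].to_numpy() for f in frames)
    pop = sum(f["population"].to_numpy() for f in frames)
    return MonthlyDeathSeries(label, base["year"].to_numpy(),
                              base["month"].to_numpy(), deaths, pop)


def run_excess_panel(
    units: list[MonthlyDeathSeries],
    fit_window=None,
    predict_window=None,
    n_boot: int = 1000,
    seed: int = 1890,
    n_harmonics: int = 1,
    pooled_label: str | None = "all_cities",
    pool_ids: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Excess tables for every unit plus a pooled "all cities" unit.

    The pooled unit sums counts and populations of ``pool_ids`` (all
    units by default, when more than one is given) before fitting, so it
    has its own baseline. Units whose series do not cover the fit window
    are skipped with a log entry. Returns (per-unit tables, winter
    summary).
    """
    work = list(units)
    if pooled_label and (pool_ids or len(units) > 1):
        members = [u for u in units
                   if pool_ids is None or u.unit_id in pool_ids]
        if len(members) > 1:
            work.append(pool_series(members, pooled_label))
    tables: dict[str, pd.DataFrame] = {}
    for i, u in enumerate(work):
        try:
            model = fit_baseline(u, fit_window, n_harmonics)
        except ValidationError as exc:
            logger.warning("skipping unit %s: %s", u.unit_id, exc)
            continue
        tab = predict_expected(model, u, predict_window,
                               n_boot=n_boot, seed=seed + i)
        tables[u.unit_id] = compute_excess(tab)
    return tables, winter_summary(tables)


def winter_summary(tables: dict[str, pd.DataFrame],
                   months: tuple[int, ...] = (12, 1, 2)) -> pd.DataFrame:
    """Dec/Jan/Feb rows of every unit's excess table, long format."""
    rows = [t[t["month"].isin(months)] for t in tables.values()]
    if not rows:
        return pd.DataFrame(columns=EXCESS_COLUMNS)
    return pd.concat(rows, ignore_index=True)
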