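"""End-to-end orchestration: simulate or load, analyse, export, log.

``run_all`` runs the whole analysis — excess-mortality tables per unit,
local G cluster tables per epidemic year, ecological determinant
regressions, cross-protection fits — writes CSV outputs with stable
column order, excess figures, a log file and a reproducibility manifest
(config + seed + package versions + input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import datamodel as dm
from . import synthetic
from .excess import run_excess_panel, EXCESS_COLUMNS
from .regression import cross_protection, results_to_frame, run_determinant_panel
from .spatial import cluster_by_year, LOCALG_COLUMNS

__all__ = ["RunConfig", "run_all", "plot_excess"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (flat-YAML friendly)."""

    out_dir: str = "results/run"
    seed: int = synthetic.DEFAULT_SEED
    # inputs: real files, or None to simulate
    monthly_csv: str | None = None
    districts_csv: str | None = None
    adjacency_csv: str | None = None
    units: list[str] | None = None
    # model settings
    fit_start: str | None = None       # "1884-12"
    fit_end: str | None = None
    predict_start: str | None = None
    predict_end: str | None = None
    n_boot: int = 1000
    n_harmonics: int = 1
    statistic: str = "gi"              # "gi" | "gi*"
    weights_scheme: str = "row_standardised"
    z_threshold: float = 1.96
    outcome_years: list[str] = field(
        default_factory=lambda: list(dm.EPIDEMIC_YEARS))
    # synthetic scenario knobs (used only when no input files are given)
    n_synthetic_units: int = 3
    scenario: dict = field(default_factory=dict)
    district_scenario: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_boot < 100:
            logger.warning("n_boot=%d < 100: prediction intervals will be "
                           "noisy", self.n_boot)
        if self.statistic not in ("gi", "gi*"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def parse_month(text: str | None) -> tuple[int, int] | None:
    """'1889-11' -> (1889, 11)."""
    if text is None:
        return None
    y, m = str(text).split("-")
    return int(y), int(m)


def _window(a, b):
    a, b = parse_month(a), parse_month(b)
    return (a, b) if a and b else None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def plot_excess(tables: dict[str, pd.DataFrame], path) -> Path:
    """One panel per unit: observed dots, expected curve, 95% PI band."""
    units = list(tables)
    if not units:
        raise ValueError("no excess tables to plot")
    ncols = min(4, len(units))
    nrows = int(np.ceil(len(units) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 2.8 * nrows),
                             squeeze=False, sharex=False)
    for ax, unit in zip(axes.ravel(), units):
        t = tables[unit]
        x = t["year"] + (t["month"] - 1) / 12.0
        ax.fill_between(x, t["pi_low"], t["pi_high"], color="0.85",
                        label="95% PI")
        ax.plot(x, t["expected"], color="0.35", lw=1.2, label="expected")
        ax.plot(x, t["observed"], color="tab:orange", lw=1.0, marker=".",
                ms=3, label="observed")
        sig = t[t["significant"] == "excess"]
        if len(sig):
            ax.axvspan(float(sig.iloc[0]["year"] + (sig.iloc[0]["month"] - 1) / 12.0) - 0.04,
                       float(sig.iloc[0]["year"] + (sig.iloc[0]["month"] - 1) / 12.0) + 0.04,
                       color="red", alpha=0.15)
        ax.set_title(unit, fontsize=9)
    for ax in axes.ravel()[len(units):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _load_or_simulate(cfg: RunConfig):
    """Return (series list, district records, weights, input checksums)."""
    checksums = {}
    if cfg.monthly_csv:
        units = cfg.units or dm.list_units(cfg.monthly_csv)
        series = [dm.read_monthly_series(cfg.monthly_csv, u) for u in units]
        checksums["monthly_csv"] = _checksum(Path(cfg.monthly_csv))
    else:
        series = []
        for k in range(cfg.n_synthetic_units):
            sc = synthetic.SeriesScenario(
                seed=cfg.seed + k, unit_id=f"unit{k + 1}", **cfg.scenario)
            series.append(synthetic.simulate_monthly_series(sc))
    if cfg.districts_csv:
        records = dm.read_district_table(cfg.districts_csv)
        checksums["districts_csv"] = _checksum(Path(cfg.districts_csv))
        edges = dm.read_adjacency_csv(cfg.adjacency_csv)
        checksums["adjacency_csv"] = _checksum(Path(cfg.adjacency_csv))
        weights = dm.build_weights(edges, ids=[r.district_id for r in records],
                                   scheme=cfg.weights_scheme)
    else:
        dsc = synthetic.DistrictScenario(seed=cfg.seed + 100,
                                         **cfg.district_scenario)
        records, weights = synthetic.simulate_district_table(
            dsc, weights_scheme=cfg.weights_scheme)
    return series, records, weights, checksums


def run_all(cfg: RunConfig) -> Path:
    """Run every stage and write tables, figures, log and manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fluexcess")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("pipeline start, seed=%d", cfg.seed)
        series, records, weights, checksums = _load_or_simulate(cfg)

        tables, summary = run_excess_panel(
            series,
            fit_window=_window(cfg.fit_start, cfg.fit_end),
            predict_window=_window(cfg.predict_start, cfg.predict_end),
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            n_harmonics=cfg.n_harmonics,
        )
        excess_long = pd.concat(tables.values(), ignore_index=True)
        excess_long.to_csv(out / "excess_monthly.csv", index=False,
                           columns=EXCESS_COLUMNS)
        summary.to_csv(out / "excess_winter_summary.csv", index=False,
                       columns=EXCESS_COLUMNS)
        logger.info("excess tables written for %d units", len(tables))

        years = [y for y in cfg.outcome_years
                 if all(y in r.flu_mortality_by_year for r in records)]
        clusters = cluster_by_year(records, weights, years,
                                   star=cfg.statistic == "gi*",
                                   z_threshold=cfg.z_threshold)
        clusters.to_csv(out / "clusters_by_year.csv", index=False,
                        columns=LOCALG_COLUMNS)
        logger.info("cluster table written: %d rows", len(clusters))

        det = []
        for year in ("1889/90", "1893/94"):
            if year in years:
                det.extend(run_determinant_panel(records, outcome_year=year))
        results_to_frame(det).to_csv(out / "determinants.csv", index=False)

        cross_rows, lines_all = [], {}
        for earlier in ("1889/90", "cumulative", "attack_rate_1890"):
            fit, lines = cross_protection(records, earlier=earlier)
            cross_rows.append(fit)
            lines_all[earlier] = lines
        results_to_frame(cross_rows).to_csv(out / "cross_protection.csv",
                                            index=False)
        logger.info("regression tables written")

        plot_excess(tables, out / "excess_curves.png")
        _plot_cluster_map(clusters, weights, out / "cluster_z.png")
        _plot_cross(records, lines_all, out / "cross_protection.png")

        manifest = {
            "config": dataclasses.asdict(cfg),
            "seed": cfg.seed,
            "versions": _versions(),
            "input_checksums": checksums,
            "outputs": sorted(p.name for p in out.iterdir()
                              if p.suffix in (".csv", ".png")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("pipeline done: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


def _versions() -> dict:
    import matplotlib as mpl
    import scipy
    import statsmodels

    return {
        "fluexcess": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": mpl.__version__,
    }


def _plot_cluster_map(clusters: pd.DataFrame, weights, path) -> None:
    """z-value heat strips per year (lattice-agnostic choropleth stand-in)."""
    years = clusters["year_label"].unique()
    fig, axes = plt.subplots(len(years), 1, figsize=(8, 1.2 * len(years)),
                             squeeze=False)
    for ax, year in zip(axes.ravel(), years):
        z = clusters.loc[clusters["year_label"] == year, "z"].to_numpy()
        ax.imshow(z[None, :], aspect="auto", cmap="RdBu_r", vmin=-4, vmax=4)
        ax.set_yticks([])
        ax.set_ylabel(year, rotation=0, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_cross(records, lines_all, path) -> None:
    from .datamodel import districts_to_frame

    df = districts_to_frame(records)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = df["flu_mort_1889_90"]
    y = df["flu_mort_1893_94"]
    urban = df["urban"].astype(bool)
    ax.scatter(x[~urban], y[~urban], s=12, color="tab:red", label="rural")
    ax.scatter(x[urban], y[urban], s=16, color="tab:blue", label="urban")
    for label, line in lines_all.get("1889/90", {}).items():
        xs = np.linspace(float(x.min()), float(x.max()), 50)
        ax.plot(xs, line["intercept"] + line["slope"] * xs,
                color="tab:blue" if label == "urban" else "tab:red")
    ax.set_xlabel("flu mortality 1889/90 (per 1000)")
    ax.set_ylabel("flu mortality 1893/94 (per 1000)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
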