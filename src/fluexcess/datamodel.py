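"""Core data types and CSV/GeoJSON input-output.

Three table kinds flow through the pipeline:

* monthly all-cause death counts with population at risk, one row per
  (unit, year, month) — the input to the seasonal Poisson baseline;
* a district table of flu-mortality outcomes per epidemic year plus
  ecological covariates — the input to hotspot clustering and the
  ecological regressions;
* district adjacency (edge list or GeoJSON polygons) from which spatial
  weights are built.

Epidemic years follow the November–October convention: the label
"1889/90" covers November 1889 through October 1890.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyDeathSeries",
    "DistrictRecord",
    "SpatialWeights",
    "FormatError",
    "ValidationError",
    "read_monthly_series",
    "write_monthly_series",
    "read_district_table",
    "write_district_table",
    "build_weights",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "adjacency_from_geojson",
    "interpolate_population",
    "EPIDEMIC_YEARS",
    "MORTALITY_COLUMNS",
    "COVARIATE_COLUMNS",
]

EPIDEMIC_YEARS = ["1889/90", "1890/91", "1891/92", "1892/93", "1893/94"]

#: CSV column name per epidemic-year label.
MORTALITY_COLUMNS = {
    "1889/90": "flu_mort_1889_90",
    "1890/91": "flu_mort_1890_91",
    "1891/92": "flu_mort_1891_92",
    "1892/93": "flu_mort_1892_93",
    "1893/94": "flu_mort_1893_94",
}

COVARIATE_COLUMNS = [
    "altitude_m",
    "density",
    "pct_over60",
    "pct_industry",
    "pct_agriculture",
    "rail_stations_per_km2",
    "gdp_per_capita",
    "hospitals_per_1000",
    "urban",
]


class FormatError(ValueError):
    """A file does not have the expected columns/structure."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


def _month_index(years: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Consecutive month counter: (year, month) -> year*12 + (month-1)."""
    return years.astype(np.int64) * 12 + (months.astype(np.int64) - 1)


@dataclass
class MonthlyDeathSeries:
    """Observed monthly all-cause deaths and population for one unit.

    ``months`` run 1–12; the (year, month) sequence must be strictly
    increasing with no gaps. Population is the person count at risk for
    each month (typically interpolated between census anchors).
    """

    unit_id: str
    years: np.ndarray
    months: np.ndarray
    deaths: np.ndarray
    population: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.months = np.asarray(self.months, dtype=np.int64)
        self.deaths = np.asarray(self.deaths)
        self.population = np.asarray(self.population, dtype=float)
        n = len(self.years)
        if not (len(self.months) == len(self.deaths) == len(self.population) == n):
            raise ValidationError(f"{self.unit_id}: field lengths differ")
        if n == 0:
            raise ValidationError(f"{self.unit_id}: empty series")
        if self.months.min() < 1 or self.months.max() > 12:
            raise ValidationError(
                f"{self.unit_id}: month outside 1..12 "
                f"(found {self.months.min()}..{self.months.max()})"
            )
        idx = _month_index(self.years, self.months)
        step = np.diff(idx)
        if np.any(step <= 0):
            k = int(np.argmax(step <= 0))
            raise ValidationError(
                f"{self.unit_id}: months not strictly increasing at "
                f"{self.years[k + 1]}-{self.months[k + 1]:02d}"
            )
        if np.any(step > 1):
            k = int(np.argmax(step > 1))
            raise ValidationError(
                f"{self.unit_id}: gap in months after "
                f"{self.years[k]}-{self.months[k]:02d}"
            )
        if np.any(self.deaths < 0):
            raise ValidationError(f"{self.unit_id}: negative death count")
        if not np.all(self.deaths == np.floor(self.deaths)):
            raise ValidationError(f"{self.unit_id}: non-integer death count")
        self.deaths = self.deaths.astype(np.int64)
        if np.any(self.population <= 0):
            raise ValidationError(f"{self.unit_id}: non-positive population")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def month_index(self) -> np.ndarray:
        return _month_index(self.years, self.months)

    def window(self, start: tuple[int, int], end: tuple[int, int]) -> "MonthlyDeathSeries":
        """Sub-series from (year, month) ``start`` to ``end`` inclusive."""
        idx = self.month_index
        lo = start[0] * 12 + start[1] - 1
        hi = end[0] * 12 + end[1] - 1
        mask = (idx >= lo) & (idx <= hi)
        if not mask.any():
            raise ValidationError(
                f"{self.unit_id}: window {start}..{end} outside series range"
            )
        return MonthlyDeathSeries(
            self.unit_id,
            self.years[mask],
            self.months[mask],
            self.deaths[mask],
            self.population[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit_id,
                "year": self.years,
                "month": self.months,
                "deaths": self.deaths,
                "population": self.population,
            }
        )


@dataclass
class DistrictRecord:
    """One district's flu-mortality outcomes and ecological covariates.

    Flu mortality is stored in deaths per 1 000 inhabitants per epidemic
    year (Nov–Oct); fractions (attack rate, age/occupation shares) are
    stored on [0, 1].
    """

    district_id: str
    flu_mortality_by_year: dict[str, float]
    attack_rate_1890: float
    altitude_m: float
    density: float
    pct_over60: float
    pct_industry: float
    pct_agriculture: float
    rail_stations_per_km2: float
    gdp_per_capita: float
    hospitals_per_1000: float
    urban: bool

    def __post_init__(self) -> None:
        for year, v in self.flu_mortality_by_year.items():
            if v < 0:
                raise ValidationError(
                    f"{self.district_id}: negative flu mortality in {year}"
                )
        for name in ("attack_rate_1890", "pct_over60", "pct_industry", "pct_agriculture"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.district_id}: {name}={v} outside [0, 1]"
                )
        if self.gdp_per_capita <= 0:
            raise ValidationError(f"{self.district_id}: non-positive GDP per capita")
        for name in ("rail_stations_per_km2", "hospitals_per_1000", "density"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.district_id}: negative {name}")


@dataclass
class SpatialWeights:
    """District adjacency with a weighting scheme for local G statistics.

    ``matrix[i, j]`` is the weight unit j carries in unit i's local
    statistic. The diagonal is nonzero only when ``self_included`` (the
    Gi* convention). ``islands`` lists units with no neighbours.
    """

    ids: list[str]
    neighbours: dict[str, set[str]]
    matrix: np.ndarray
    scheme: str  # "binary" | "row_standardised"
    self_included: bool
    islands: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, district_id: str) -> int:
        return self.ids.index(district_id)

    def subset(self, ids: list[str]) -> "SpatialWeights":
        """Restrict to ``ids`` (re-standardising rows if applicable)."""
        edges = [
            (a, b)
            for a in ids
            for b in self.neighbours.get(a, ())
            if b in set(ids) and a < b
        ]
        return build_weights(edges, ids=ids, scheme=self.scheme,
                             self_included=self.self_included)


# ---------------------------------------------------------------------------
# monthly series IO

_MONTHLY_COLS = ["unit", "year", "month", "deaths", "population"]


def read_monthly_series(path, unit_id: str) -> MonthlyDeathSeries:
    """Read one unit's series from a long-format monthly-deaths CSV."""
    df = pd.read_csv(path)
    missing = set(_MONTHLY_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sub = df[df["unit"].astype(str) == unit_id]
    if sub.empty:
        raise ValidationError(f"{path}: unit {unit_id!r} not present")
    sub = sub.sort_values(["year", "month"])
    dup = sub.duplicated(subset=["year", "month"])
    if dup.any():
        r = sub[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicated month {int(r.year)}-{int(r.month):02d} "
            f"for unit {unit_id!r}"
        )
    return MonthlyDeathSeries(
        unit_id,
        sub["year"].to_numpy(),
        sub["month"].to_numpy(),
        sub["deaths"].to_numpy(),
        sub["population"].to_numpy(),
    )


def list_units(path) -> list[str]:
    """Unit ids present in a monthly-deaths CSV, in file order."""
    units = pd.read_csv(path, usecols=["unit"])["unit"].astype(str)
    return list(dict.fromkeys(units))


def write_monthly_series(series: list[MonthlyDeathSeries] | MonthlyDeathSeries, path) -> None:
    if isinstance(series, MonthlyDeathSeries):
        series = [series]
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False, columns=_MONTHLY_COLS
    )


# ---------------------------------------------------------------------------
# district table IO

def _district_to_row(r: DistrictRecord) -> dict:
    row = {"district_id": r.district_id}
    for year, col in MORTALITY_COLUMNS.items():
        row[col] = r.flu_mortality_by_year.get(year, np.nan)
    row["attack_rate_pct_1890"] = 100.0 * r.attack_rate_1890
    for c in COVARIATE_COLUMNS:
        row[c] = getattr(r, c)
    row["pct_over60"] = 100.0 * r.pct_over60
    row["pct_industry"] = 100.0 * r.pct_industry
    row["pct_agriculture"] = 100.0 * r.pct_agriculture
    row["urban"] = int(r.urban)
    return row


def read_district_table(path) -> list[DistrictRecord]:
    """Read the district outcome/covariate table.

    Percent columns (attack rate, population shares) are divided by 100;
    a ``mortality_units`` column with value ``per_10000`` triggers a ÷10
    conversion so that mortality is always stored per 1 000.
    """
    df = pd.read_csv(path)
    required = (
        ["district_id"]
        + list(MORTALITY_COLUMNS.values())
        + ["attack_rate_pct_1890"]
        + COVARIATE_COLUMNS
    )
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    ids = df["district_id"].astype(str)
    if ids.duplicated().any():
        raise ValidationError(
            f"{path}: duplicate district_id {ids[ids.duplicated()].iloc[0]!r}"
        )
    if len(df) < 2:
        raise ValidationError(f"{path}: need at least 2 districts, got {len(df)}")
    bad = (df["attack_rate_pct_1890"] < 0) | (df["attack_rate_pct_1890"] > 100)
    if bad.any():
        raise ValidationError(
            f"{path}: attack rate outside [0, 100]% for district "
            f"{ids[bad].iloc[0]!r}"
        )
    divisor = 1.0
    if "mortality_units" in df.columns:
        units = set(df["mortality_units"].astype(str).unique())
        if units == {"per_10000"}:
            divisor = 10.0
        elif units != {"per_1000"}:
            raise FormatError(f"{path}: unrecognised mortality_units {units}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DistrictRecord(
                district_id=str(row["district_id"]),
                flu_mortality_by_year={
                    year: float(row[col]) / divisor
                    for year, col in MORTALITY_COLUMNS.items()
                    if pd.notna(row[col])
                },
                attack_rate_1890=float(row["attack_rate_pct_1890"]) / 100.0,
                altitude_m=float(row["altitude_m"]),
                density=float(row["density"]),
                pct_over60=float(row["pct_over60"]) / 100.0,
                pct_industry=float(row["pct_industry"]) / 100.0,
                pct_agriculture=float(row["pct_agriculture"]) / 100.0,
                rail_stations_per_km2=float(row["rail_stations_per_km2"]),
                gdp_per_capita=float(row["gdp_per_capita"]),
                hospitals_per_1000=float(row["hospitals_per_1000"]),
                urban=bool(int(row["urban"])),
            )
        )
    return records


def write_district_table(records: list[DistrictRecord], path) -> None:
    cols = (
        ["district_id"]
        + list(MORTALITY_COLUMNS.values())
        + ["attack_rate_pct_1890"]
        + COVARIATE_COLUMNS
    )
    pd.DataFrame([_district_to_row(r) for r in records]).to_csv(
        path, index=False, columns=cols
    )


def districts_to_frame(records: list[DistrictRecord]) -> pd.DataFrame:
    """Analysis-ready frame: fractions on [0,1], one column per outcome."""
    rows = []
    for r in records:
        row = {
            "district_id": r.district_id,
            "attack_rate_1890": r.attack_rate_1890,
            "altitude_m": r.altitude_m,
            "density": r.density,
            "pct_over60": r.pct_over60,
            "pct_industry": r.pct_industry,
            "pct_agriculture": r.pct_agriculture,
            "rail_stations_per_km2": r.rail_stations_per_km2,
            "gdp_per_capita": r.gdp_per_capita,
            "hospitals_per_1000": r.hospitals_per_1000,
            "urban": r.urban,
        }
        for year, col in MORTALITY_COLUMNS.items():
            row[col] = r.flu_mortality_by_year.get(year, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial weights

def build_weights(
    adjacency,
    ids: list[str] | None = None,
    scheme: str = "row_standardised",
    self_included: bool = False,
) -> SpatialWeights:
    """Build spatial weights from an undirected edge list.

    ``adjacency`` is an iterable of (id_a, id_b) pairs. ``ids`` fixes the
    unit ordering (and brings in units with no edges); by default the
    ordering is first appearance in the edge list. With
    ``scheme="row_standardised"`` every row of the matrix sums to 1 over
    the unit's neighbours (plus itself when ``self_included``). Units
    without neighbours are flagged as islands (warning, zero row).
    """
    if scheme not in ("binary", "row_standardised"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    edges = [(str(a), str(b)) for a, b in adjacency]
    if ids is None:
        seen: dict[str, None] = {}
        for a, b in edges:
            seen.setdefault(a)
            seen.setdefault(b)
        ids = list(seen)
    else:
        ids = [str(i) for i in ids]
        known = set(ids)
        for a, b in edges:
            if a not in known or b not in known:
                raise ValidationError(
                    f"adjacency references unknown district {a if a not in known else b!r}"
                )
    pos = {d: k for k, d in enumerate(ids)}
    neighbours: dict[str, set[str]] = {d: set() for d in ids}
    for a, b in edges:
        if a == b:
            continue
        neighbours[a].add(b)
        neighbours[b].add(a)
    n = len(ids)
    m = np.zeros((n, n))
    for d, nbrs in neighbours.items():
        i = pos[d]
        for b in nbrs:
            m[i, pos[b]] = 1.0
    if self_included:
        np.fill_diagonal(m, 1.0)
    islands = [d for d in ids if not neighbours[d]]
    if islands:
        warnings.warn(
            f"{len(islands)} island district(s) with no neighbours: "
            f"{islands[:5]}", stacklevel=2
        )
    if scheme == "row_standardised":
        rowsum = m.sum(axis=1, keepdims=True)
        np.divide(m, rowsum, out=m, where=rowsum > 0)
    return SpatialWeights(ids, neighbours, m, scheme, self_included, islands)


def read_adjacency_csv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path)
    if not {"id_a", "id_b"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns id_a,id_b")
    return list(zip(df["id_a"].astype(str), df["id_b"].astype(str)))


def write_adjacency_csv(edges: list[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["id_a", "id_b"]).to_csv(path, index=False)


def adjacency_from_geojson(path_or_obj) -> list[tuple[str, str]]:
    """Queen-contiguity edge list from a GeoJSON FeatureCollection.

    Each feature needs a ``district_id`` property; polygons sharing any
    boundary point are neighbours.
    """
    from shapely.geometry import shape

    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    feats = obj["features"]
    geoms, gids = [], []
    for f in feats:
        props = f.get("properties", {})
        if "district_id" not in props:
            raise FormatError("GeoJSON feature lacks district_id property")
        gids.append(str(props["district_id"]))
        geoms.append(shape(f["geometry"]))
    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].intersects(geoms[j]) and not geoms[i].equals(geoms[j]):
                edges.append((gids[i], gids[j]))
    return edges


# ---------------------------------------------------------------------------
# population interpolation

def interpolate_population(
    anchor_years: np.ndarray,
    anchor_pops: np.ndarray,
    years: np.ndarray,
    months: np.ndarray,
    anchor_month: int = 6,
) -> np.ndarray:
    """Monthly population by linear interpolation between annual anchors.

    Each anchor value is pinned to (year, ``anchor_month``); interpolation
    is linear in the month index between anchors and constant beyond the
    first/last anchor. Exact at anchors, monotone between adjacent ones.
    """
    anchor_years = np.asarray(anchor_years, dtype=float)
    anchor_pops = np.asarray(anchor_pops, dtype=float)
    if len(anchor_years) == 0 or len(anchor_years) != len(anchor_pops):
        raise ValidationError("population anchors malformed")
    order = np.argsort(anchor_years)
    ax = anchor_years[order] * 12 + (anchor_month - 1)
    ay = anchor_pops[order]
    t = np.asarray(years, dtype=float) * 12 + (np.asarray(months, dtype=float) - 1)
    return np.interp(t, ax, ay)
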