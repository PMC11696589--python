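"""Getis-Ord local G hotspot statistics over district rates.

For unit i with spatial weights w_ij the local statistic is reported as
a z-value under the normality approximation:

    z_i = (sum_j w_ij x_j - xbar_i W_i)
          / ( s_i * sqrt[ (n_i * sum_j w_ij^2 - W_i^2) / (n_i - 1) ] )

In the Gi convention the sums run over j != i and xbar_i, s_i are the
mean and standard deviation of the other n_i = n - 1 values; in the Gi*
convention the unit's own value is included (j over all units,
n_i = n). Large positive z marks a cluster of high values (hotspot),
large negative z a coldspot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DistrictRecord, SpatialWeights, ValidationError, districts_to_frame, MORTALITY_COLUMNS

__all__ = ["local_g", "classify_clusters", "cluster_by_year",
           "permutation_pvalues", "LOCALG_COLUMNS"]

LOCALG_COLUMNS = ["district_id", "year_label", "value", "z", "cluster",
                  "n_neighbours"]


def _weight_matrix(weights: SpatialWeights, star: bool) -> np.ndarray:
    """Weight matrix with the diagonal convention the statistic needs.

    Gi needs a zero diagonal; Gi* needs a self weight — when the
    supplied weights exclude self, a unit self-weight is added and rows
    are re-standardised under the row-standardised scheme.
    """
    w = weights.matrix.copy()
    if not star:
        np.fill_diagonal(w, 0.0)
        if weights.self_included and weights.scheme == "row_standardised":
            rs = w.sum(axis=1, keepdims=True)
            np.divide(w, rs, out=w, where=rs > 0)
    elif not weights.self_included:
        if weights.scheme == "row_standardised":
            # recover binary structure, add self, re-standardise
            b = (w > 0).astype(float)
            np.fill_diagonal(b, 1.0)
            w = b / b.sum(axis=1, keepdims=True)
        else:
            np.fill_diagonal(w, 1.0)
    return w


def local_g(
    values: np.ndarray,
    weights: SpatialWeights,
    star: bool = False,
    year_label: str = "",
) -> pd.DataFrame:
    """Local G z-values for one cross-section of district rates.

    ``values`` must align with ``weights.ids``. Units with no
    neighbours get z = NaN and cluster "none". Adding a constant to all
    values, or scaling them by a positive constant, leaves z unchanged.
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise ValidationError(f"{len(x)} values for {n} districts")
    if np.var(x) == 0:
        raise ValidationError("zero variance in values: local G undefined")
    w = _weight_matrix(weights, star)
    Wi = w.sum(axis=1)
    S1 = (w ** 2).sum(axis=1)
    lag = w @ x
    if star:
        ni = np.full(n, n, dtype=float)
        xbar = np.full(n, x.mean())
        s2 = np.full(n, x.var())  # population variance over all n
    else:
        ni = np.full(n, n - 1, dtype=float)
        xbar = (x.sum() - x) / (n - 1)
        s2 = (np.sum(x ** 2) - x ** 2) / (n - 1) - xbar ** 2
    s2 = np.maximum(s2, 0.0)
    denom2 = s2 * (ni * S1 - Wi ** 2) / (ni - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (lag - xbar * Wi) / np.sqrt(denom2)
    n_nbrs = np.array([len(weights.neighbours[d]) for d in weights.ids])
    z = np.where(n_nbrs == 0, np.nan, z)
    out = pd.DataFrame(
        {
            "district_id": weights.ids,
            "year_label": year_label,
            "value": x,
            "z": z,
            "cluster": "none",
            "n_neighbours": n_nbrs,
        }
    )
    return classify_clusters(out)


def classify_clusters(results: pd.DataFrame, z_threshold: float = 1.96) -> pd.DataFrame:
    """Label hotspots/coldspots: high iff z > threshold, low iff z < -threshold."""
    out = results.copy()
    z = out["z"].to_numpy(dtype=float)
    out["cluster"] = np.select(
        [z > z_threshold, z < -z_threshold], ["high", "low"], default="none"
    )
    out.loc[~np.isfinite(z), "cluster"] = "none"
    return out


def cluster_by_year(
    districts: list[DistrictRecord],
    weights: SpatialWeights,
    years: list[str] | None = None,
    star: bool = False,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Local G per district and epidemic year, long format.

    District order follows ``weights.ids``; every requested year must be
    present in each district's mortality map.
    """
    if years is None:
        years = list(MORTALITY_COLUMNS)
    by_id = {d.district_id: d for d in districts}
    missing = [i for i in weights.ids if i not in by_id]
    if missing:
        raise ValidationError(f"districts missing from table: {missing[:5]}")
    frames = []
    for year in years:
        vals = []
        for i in weights.ids:
            m = by_id[i].flu_mortality_by_year
            if year not in m:
                raise ValidationError(
                    f"district {i}: no flu mortality for year {year!r}"
                )
            vals.append(m[year])
        res = local_g(np.array(vals), weights, star=star, year_label=year)
        frames.append(classify_clusters(res, z_threshold))
    return pd.concat(frames, ignore_index=True)


def permutation_pvalues(
    values: np.ndarray,
    weights: SpatialWeights,
    star: bool = False,
    n_perm: int = 999,
    seed: int = 1890,
) -> np.ndarray:
    """Two-sided conditional permutation p-values for the local G z-values.

    Values are randomly reassigned to units (holding each unit's own
    value fixed in the Gi convention is implicit since Gi excludes self);
    the p-value is the fraction of permutations with |z| at least as
    extreme, with the observed arrangement counted once.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    z_obs = local_g(x, weights, star=star)["z"].to_numpy()
    count = np.zeros(len(x))
    for _ in range(n_perm):
        z_p = local_g(rng.permutation(x), weights, star=star)["z"].to_numpy()
        count += np.abs(z_p) >= np.abs(z_obs)
    return (count + 1.0) / (n_perm + 1.0)


def results_to_geojson(results: pd.DataFrame, geojson_obj: dict) -> dict:
    """Attach z and cluster labels to a GeoJSON FeatureCollection in place."""
    by_id = results.set_index("district_id")
    for feat in geojson_obj["features"]:
        did = str(feat["properties"]["district_id"])
        if did in by_id.index:
            row = by_id.loc[did]
            feat["properties"]["z"] = float(row["z"])
            feat["properties"]["cluster"] = str(row["cluster"])
    return geojson_obj
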