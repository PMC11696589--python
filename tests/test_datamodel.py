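"""Data types, CSV/GeoJSON IO, spatial weights and population interpolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluexcess import datamodel as dm
from fluexcess.synthetic import DistrictScenario, simulate_district_table


def _series_frame(n=120, start=(1885, 1), unit="CH"):
    t = np.arange(n)
    return pd.DataFrame({
        "unit": unit,
        "year": start[0] + (start[1] - 1 + t) // 12,
        "month": (start[1] - 1 + t) % 12 + 1,
        "deaths": 100 + (t % 12),
        "population": 1e5 + 10.0 * t,
    })


class TestMonthlySeries:
    def test_round_trip_preserves_counts(self, tmp_path):
        path = tmp_path / "monthly.csv"
        _series_frame().to_csv(path, index=False)
        s = dm.read_monthly_series(path, "CH")
        assert len(s) == 120
        dm.write_monthly_series(s, tmp_path / "rt.csv")
        s2 = dm.read_monthly_series(tmp_path / "rt.csv", "CH")
        np.testing.assert_array_equal(s.deaths, s2.deaths)
        np.testing.assert_allclose(s.population, s2.population)
        np.testing.assert_array_equal(s.month_index, s2.month_index)

    @pytest.mark.parametrize("corrupt,err", [
        (lambda df: df.assign(month=df.month.where(df.index != 3, 13)),
         "month"),
        (lambda df: df.drop(index=5), "gap"),
        (lambda df: df.assign(deaths=df.deaths.where(df.index != 2, -1)),
         "negative"),
    ])
    def test_invalid_series_rejected(self, tmp_path, corrupt, err):
        path = tmp_path / "bad.csv"
        corrupt(_series_frame(n=24)).to_csv(path, index=False)
        with pytest.raises(dm.ValidationError, match=err):
            dm.read_monthly_series(path, "CH")

    def test_duplicate_month_rejected(self, tmp_path):
        df = _series_frame(n=24)
        pd.concat([df, df.iloc[[4]]]).to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(dm.ValidationError, match="duplicated"):
            dm.read_monthly_series(tmp_path / "dup.csv", "CH")

    def test_missing_column_is_format_error(self, tmp_path):
        _series_frame(24).drop(columns="population").to_csv(
            tmp_path / "nc.csv", index=False)
        with pytest.raises(dm.FormatError, match="population"):
            dm.read_monthly_series(tmp_path / "nc.csv", "CH")


class TestDistrictTable:
    def test_round_trip_on_synthetic_panel(self, tmp_path, district_panel):
        records, _ = district_panel
        path = tmp_path / "districts.csv"
        dm.write_district_table(records, path)
        back = dm.read_district_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.district_id == b.district_id
            assert a.urban == b.urban
            np.testing.assert_allclose(a.attack_rate_1890, b.attack_rate_1890,
                                       rtol=1e-9)
            for year, v in a.flu_mortality_by_year.items():
                np.testing.assert_allclose(v, b.flu_mortality_by_year[year],
                                           rtol=1e-9)

    def test_percent_columns_become_fractions(self, tmp_path, district_panel):
        records, _ = district_panel
        path = tmp_path / "districts.csv"
        dm.write_district_table(records[:5], path)
        df = pd.read_csv(path)
        df.loc[0, "attack_rate_pct_1890"] = 61.0
        df.to_csv(path, index=False)
        back = dm.read_district_table(path)
        assert back[0].attack_rate_1890 == pytest.approx(0.61)

    def test_per_10000_units_flag_converts(self, tmp_path, district_panel):
        records, _ = district_panel
        path = tmp_path / "districts.csv"
        dm.write_district_table(records[:5], path)
        df = pd.read_csv(path)
        per1000 = df["flu_mort_1889_90"].copy()
        df["flu_mort_1889_90"] = per1000 * 10
        df["mortality_units"] = "per_10000"
        # other year columns intentionally left as-is times 10 too
        for c in dm.MORTALITY_COLUMNS.values():
            if c != "flu_mort_1889_90":
                df[c] = df[c] * 10
        df.to_csv(path, index=False)
        back = dm.read_district_table(path)
        got = [r.flu_mortality_by_year["1889/90"] for r in back]
        np.testing.assert_allclose(got, per1000, rtol=1e-9)

    def test_duplicate_and_out_of_range_rejected(self, tmp_path, district_panel):
        records, _ = district_panel
        path = tmp_path / "districts.csv"
        dm.write_district_table(records[:4] + records[:1], path)
        with pytest.raises(dm.ValidationError, match="duplicate"):
            dm.read_district_table(path)
        dm.write_district_table(records[:4], path)
        df = pd.read_csv(path)
        df.loc[1, "attack_rate_pct_1890"] = 140.0
        df.to_csv(path, index=False)
        with pytest.raises(dm.ValidationError, match="attack rate"):
            dm.read_district_table(path)


class TestSpatialWeights:
    def test_rook_lattice_neighbour_counts(self):
        from fluexcess.synthetic import lattice_adjacency

        edges, ids = lattice_adjacency(3, 3)
        w = dm.build_weights(edges, ids=ids, scheme="binary")
        counts = sorted(len(w.neighbours[i]) for i in ids)
        # 4 corners with 2, 4 edges with 3, centre with 4
        assert counts == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_row_standardised_rows_sum_to_one(self):
        from fluexcess.synthetic import lattice_adjacency

        edges, ids = lattice_adjacency(3, 3)
        w = dm.build_weights(edges, ids=ids, scheme="row_standardised")
        np.testing.assert_allclose(w.matrix.sum(axis=1), 1.0, atol=1e-12)
        ws = dm.build_weights(edges, ids=ids, scheme="row_standardised",
                              self_included=True)
        np.testing.assert_allclose(ws.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(ws.matrix) > 0)

    def test_geojson_polygons_match_edge_list(self):
        # four unit squares in a 2x2 block: rook edges between touching sides
        def square(x, y):
            return {"type": "Polygon", "coordinates": [[
                [x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]]}

        gj = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"district_id": d},
             "geometry": square(*xy)}
            for d, xy in [("A", (0, 0)), ("B", (1, 0)), ("C", (0, 1)),
                          ("D", (1, 1))]]}
        edges = dm.adjacency_from_geojson(gj)
        w_geo = dm.build_weights(edges, ids=["A", "B", "C", "D"],
                                 scheme="binary")
        # queen contiguity: all four touch (diagonals share the centre point)
        w_hand = dm.build_weights(
            [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
             ("C", "D")], ids=["A", "B", "C", "D"], scheme="binary")
        np.testing.assert_array_equal(w_geo.matrix, w_hand.matrix)

    def test_island_flagged_and_unknown_id_rejected(self):
        with pytest.warns(UserWarning, match="island"):
            w = dm.build_weights([("A", "B")], ids=["A", "B", "C"])
        assert w.islands == ["C"]
        with pytest.raises(dm.ValidationError, match="unknown"):
            dm.build_weights([("A", "X")], ids=["A", "B"])


class TestPopulationInterpolation:
    def test_exact_at_anchors(self):
        pop = dm.interpolate_population(
            [1880, 1888, 1890], [2.6e6, 2.9e6, 2.95e6],
            np.array([1880, 1888, 1890]), np.array([6, 6, 6]))
        np.testing.assert_allclose(pop, [2.6e6, 2.9e6, 2.95e6])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e4, max_value=1e7),
                    min_size=2, max_size=6))
    def test_monotone_between_anchors_and_constant_outside(self, pops):
        years = np.arange(1880, 1880 + len(pops))
        t_years = np.repeat(np.arange(1878, 1882 + len(pops)), 12)
        t_months = np.tile(np.arange(1, 13), len(t_years) // 12)
        out = dm.interpolate_population(years, pops, t_years, t_months)
        # constant extrapolation at the ends
        assert out[0] == pops[0]
        assert out[-1] == pops[-1]
        # piecewise monotone: every month step moves toward the next anchor
        d = np.diff(out)
        anchors = np.sort(years * 12 + 5)
        t = t_years * 12 + t_months - 1
        for k in range(len(anchors) - 1):
            seg = (t[:-1] >= anchors[k]) & (t[1:] <= anchors[k + 1])
            sgn = np.sign(pops[k + 1] - pops[k])
            assert np.all(sgn * d[seg] >= 0)
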