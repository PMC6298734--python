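"""Projection, grid tiling, abundance standardization and the S index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nichepart as nip
from nichepart import grid as gmod
from nichepart.grid import TransverseMercator


class TestProjection:
    def test_central_meridian_maps_to_false_easting(self):
        proj = TransverseMercator.utm_zone(5)  # lon0 = -153
        x, y = proj.forward(-153.0, np.array([52.0, 57.0, 60.0]))
        assert np.allclose(x, 500_000.0, atol=1e-6)
        assert np.all(np.diff(y) > 0)

    def test_roundtrip(self):
        proj = TransverseMercator.utm_zone(5)
        rng = np.random.default_rng(0)
        lon = rng.uniform(-159, -147, 200)
        lat = rng.uniform(50, 62, 200)
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        # series truncation leaves sub-meter residuals, irrelevant at 100 km
        assert np.abs(lon - lon2).max() < 2e-6
        assert np.abs(lat - lat2).max() < 2e-6

    def test_meridian_scale_factor(self):
        # northing along the central meridian advances at k0 times the
        # ellipsoidal meridian arc (~110.9-111.4 km per degree)
        proj = TransverseMercator.utm_zone(5)
        _, y1 = proj.forward(-153.0, 56.0)
        _, y2 = proj.forward(-153.0, 57.0)
        per_degree = (y2 - y1) / 0.9996
        assert 110_500 < per_degree < 111_800

    def test_zone_for_longitude(self):
        proj = TransverseMercator.for_longitude(-153.0)
        assert proj.lon0 == -153.0  # zone 5N central meridian


class TestGridTiling:
    def test_forced_two_cell_tiling(self):
        proj = TransverseMercator.utm_zone(5)
        # an extent whose projected bounding box spans ~160 x 60 km
        lon_w, lat_s = proj.inverse(420_000.0, 6_220_000.0)
        lon_e, lat_n = proj.inverse(580_000.0, 6_280_000.0)
        grid = gmod.build_grid(
            (float(lon_w), float(lon_e), float(lat_s), float(lat_n)),
            cell_size=100_000.0, projection=proj,
        )
        assert grid.n_cols == 2
        assert grid.n_rows == 1

    def test_cell_center_locates_to_its_cell(self, goa_grid):
        cells = goa_grid.cells()
        ids = goa_grid.locate(cells["center_lon"].to_numpy(),
                              cells["center_lat"].to_numpy())
        assert list(ids) == list(cells["cell_id"])

    def test_locate_matches_interval_oracle(self, goa_grid):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-169, -133, 300)
        lat = rng.uniform(52.5, 59.5, 300)
        got = goa_grid.locate(lon, lat)
        x, y = goa_grid.projection.forward(lon, lat)
        for xi, yi, gi in zip(np.atleast_1d(x), np.atleast_1d(y), got):
            col = int(np.floor((xi - goa_grid.x0) / goa_grid.cell_size))
            row = int(np.floor((yi - goa_grid.y0) / goa_grid.cell_size))
            if 0 <= col < goa_grid.n_cols and 0 <= row < goa_grid.n_rows:
                assert gi == f"c{col}_r{row}"
            else:
                assert gi == "unassigned"

    def test_point_outside_unassigned(self, goa_grid):
        assert goa_grid.locate(10.0, -40.0) == "unassigned"


class TestCellYearEnv:
    def test_single_and_double_haul_means(self, goa_grid):
        hauls = pd.DataFrame(
            dict(
                haul_id=["a", "b", "c"],
                year=[1999, 1999, 2001],
                lon=[-150.0, -150.0001, -150.0],
                lat=[55.0, 55.0001, 55.0],
                depth_m=[100.0, 200.0, 321.0],
                temp_c=[4.0, 6.0, 5.5],
            )
        )
        env = gmod.cell_year_env(hauls, goa_grid)
        assert len(env) == 2
        r99 = env[env.year == 1999].iloc[0]
        assert r99.depth_m == pytest.approx(150.0)
        assert r99.temp_c == pytest.approx(5.0)
        assert r99.n_hauls == 2
        r01 = env[env.year == 2001].iloc[0]
        assert r01.depth_m == pytest.approx(321.0)

    def test_matches_groupby_oracle(self, survey_tables, goa_grid):
        hauls = survey_tables["hauls"].dropna(subset=["depth_m", "temp_c"])
        env = gmod.cell_year_env(hauls, goa_grid)
        ids = goa_grid.locate(hauls["lon"].to_numpy(), hauls["lat"].to_numpy())
        sample = env.sample(10, random_state=0)
        for _, row in sample.iterrows():
            mask = (ids == row.cell_id) & (hauls["year"] == row.year).to_numpy()
            assert hauls.loc[mask, "depth_m"].mean() == pytest.approx(row.depth_m)
            assert int(mask.sum()) == row.n_hauls


def _field(values, species="PH"):
    years = [2001 + i for i in range(len(values))]
    return pd.DataFrame(
        dict(species=species, year=years, cell_id="c0_r0",
             po=1.0, pa=np.asarray(values, dtype=float))
    )


class TestStandardization:
    def test_forced_arithmetic_max(self):
        out = gmod.combine_and_standardize(_field([2, 4, 8]), method="max")
        assert list(out["std_abundance"]) == [0.25, 0.5, 1.0]

    def test_scale_equivariance_across_methods(self):
        field = _field([1.5, 3.0, 4.5, 9.0])
        by = {
            m: gmod.combine_and_standardize(field, method=m)["std_abundance"]
            for m in ("max", "mean", "median")
        }
        ratio_mean = (by["mean"] / by["max"]).to_numpy()
        ratio_med = (by["median"] / by["max"]).to_numpy()
        assert np.ptp(ratio_mean) < 1e-12
        assert np.ptp(ratio_med) < 1e-12

    def test_rank_order_invariant_across_methods(self):
        rng = np.random.default_rng(3)
        field = _field(rng.exponential(2.0, 40))
        orders = [
            np.argsort(
                gmod.combine_and_standardize(field, method=m)["std_abundance"]
            ).to_numpy()
            for m in ("max", "mean", "median")
        ]
        assert (orders[0] == orders[1]).all()
        assert (orders[0] == orders[2]).all()

    def test_max_field_attains_one(self):
        rng = np.random.default_rng(4)
        field = _field(rng.exponential(1.0, 25))
        out = gmod.combine_and_standardize(field, method="max")
        assert out["std_abundance"].max() == pytest.approx(1.0)
        assert ((out["std_abundance"] >= 0) & (out["std_abundance"] <= 1)).all()

    def test_all_zero_species_rejected(self):
        with pytest.raises(ValueError, match="standardizer undefined"):
            gmod.combine_and_standardize(_field([0.0, 0.0]))


def _two_species_field(rows):
    """rows: list of (year, cell, stdA_PH, stdA_ATF)."""
    recs = []
    for year, cell, a, b in rows:
        recs.append(dict(species="PH", year=year, cell_id=cell,
                         std_abundance=a))
        recs.append(dict(species="ATF", year=year, cell_id=cell,
                         std_abundance=b))
    return pd.DataFrame(recs)


class TestHabitatExclusion:
    def test_low_both_all_years_excluded(self):
        field = _two_species_field([(1, "x", 0.1, 0.1), (2, "x", 0.2, 0.05)])
        retained, excluded = gmod.exclude_low_habitat(field, ("PH", "ATF"))
        assert excluded == ["x"]
        assert retained == []

    def test_one_species_above_any_year_retained(self):
        field = _two_species_field([(1, "x", 0.1, 0.1), (2, "x", 0.3, 0.05)])
        retained, excluded = gmod.exclude_low_habitat(field, ("PH", "ATF"))
        assert retained == ["x"]

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(5)
        rows = [
            (y, f"c{c}", rng.random() * 0.6, rng.random() * 0.6)
            for c in range(30) for y in (1, 2, 3)
        ]
        field = _two_species_field(rows)
        retained, excluded = gmod.exclude_low_habitat(field, ("PH", "ATF"),
                                                      threshold=0.25)
        for cell in {r[1] for r in rows}:
            cell_rows = [r for r in rows if r[1] == cell]
            drop = all(a < 0.25 and b < 0.25 for _, _, a, b in cell_rows)
            assert (cell in excluded) == drop


class TestSpatialOverlap:
    def test_forced_products(self):
        field = _two_species_field(
            [(1, "x", 1.0, 1.0), (1, "y", 0.7, 0.0), (1, "z", 0.5, 0.4)]
        )
        ov = gmod.spatial_overlap(field, ("PH", "ATF"))
        s = ov.set_index("cell_id")["s"]
        assert s["x"] == pytest.approx(1.0)
        assert s["y"] == pytest.approx(0.0)
        assert s["z"] == pytest.approx(0.2)

    def test_symmetric_in_species(self):
        field = _two_species_field([(1, "x", 0.8, 0.3), (2, "x", 0.2, 0.9)])
        a = gmod.spatial_overlap(field, ("PH", "ATF"))["s"]
        b = gmod.spatial_overlap(field, ("ATF", "PH"))["s"]
        assert np.allclose(a, b)

    def test_mismatched_index_sets_rejected(self):
        field = _two_species_field([(1, "x", 0.8, 0.3)])
        field = pd.concat(
            [field, pd.DataFrame([dict(species="PH", year=2, cell_id="y",
                                       std_abundance=0.5)])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="mismatched"):
            gmod.spatial_overlap(field, ("PH", "ATF"))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)),
            min_size=1, max_size=30,
        )
    )
    def test_s_in_unit_interval_property(self, pairs):
        rows = [(1, f"c{i}", a, b) for i, (a, b) in enumerate(pairs)]
        ov = gmod.spatial_overlap(_two_species_field(rows), ("PH", "ATF"))
        assert ((ov["s"] >= 0) & (ov["s"] <= 1)).all()
        for (_, _, a, b), s in zip(rows, ov.sort_values("cell_id",
                                                        key=lambda c: c.str[1:].astype(int))["s"]):
            if a == 0 or b == 0:
                assert s == 0

    def test_cell_means(self):
        field = _two_species_field([(1, "x", 0.5, 0.4), (2, "x", 1.0, 0.8)])
        ov = gmod.spatial_overlap(field, ("PH", "ATF"))
        cm = gmod.cell_means(ov)
        assert cm["mean_s"].iloc[0] == pytest.approx((0.2 + 0.8) / 2)
        assert cm["n_years"].iloc[0] == 2
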