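"""Geographic/environmental covariates: geometry, raster CVs, design, VIF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

from avian_itv import covariates
from avian_itv.covariates import (
    distance_to_edge,
    spatial_cv,
    temporal_cv,
    vif,
)


class TestDistanceToEdge:
    def test_center_of_square(self):
        sq = box(0, 0, 100, 100)
        assert distance_to_edge((50, 50), sq) == pytest.approx(50.0, abs=1e-6)

    def test_outside_polygon_is_zero(self):
        sq = box(0, 0, 100, 100)
        assert distance_to_edge((150, 50), sq) == 0.0

    def test_small_hole_closed_by_buffer(self):
        """An 8-km hole is erased: distance equals the brute-force distance
        to the boundary of the morphologically closed polygon."""
        outer = box(0, 0, 200, 200)
        hole = Point(100, 100).buffer(4.0)  # 8-km diameter
        poly = Polygon(outer.exterior.coords,
                       [list(hole.exterior.coords)])
        pt = (100, 106)  # right next to the hole
        d = distance_to_edge(pt, poly, buffer_km=10)
        closed = poly.buffer(10).buffer(-10)  # independent closing oracle
        expected = Point(pt).distance(closed.exterior)
        assert d == pytest.approx(expected, abs=0.05)
        # and the hole, not the outer edge, would dominate without closing
        assert Point(pt).distance(poly.boundary) < expected

    def test_large_hole_still_counts(self):
        outer = box(0, 0, 200, 200)
        hole = Point(100, 100).buffer(30.0)
        poly = Polygon(outer.exterior.coords, [list(hole.exterior.coords)])
        pt = (100, 140)
        d = distance_to_edge(pt, poly, buffer_km=10)
        assert d == pytest.approx(10.0, abs=0.1)  # 140 - (100+30)

    def test_lonlat_projection_close_to_planar(self):
        # a ~1x1 degree box at 45N, point near its centre
        sq = box(-100.5, 44.5, -99.5, 45.5)
        d = distance_to_edge((-100.0, 45.0), sq, crs="lonlat")
        # half a degree of latitude ~ 55.7 km; EW extent is shorter (cos 45)
        assert d == pytest.approx(0.5 * 111.32 * np.cos(np.radians(45.0)), rel=0.02)

    @settings(max_examples=25, deadline=None)
    @given(
        x1=st.floats(10, 90), y1=st.floats(10, 90),
        x2=st.floats(10, 90), y2=st.floats(10, 90),
    )
    def test_lipschitz_in_point(self, x1, y1, x2, y2):
        """|d(p1) - d(p2)| <= |p1 - p2| (planar metric)."""
        sq = box(0, 0, 100, 100)
        d1 = distance_to_edge((x1, y1), sq)
        d2 = distance_to_edge((x2, y2), sq)
        assert abs(d1 - d2) <= np.hypot(x1 - x2, y1 - y2) + 1e-9


def _raster(cells):
    """cells: list of (x, y, year, value)."""
    return pd.DataFrame(cells, columns=["x", "y", "year", "value"])


class TestRasterCVs:
    def test_spatially_uniform_means_zero(self):
        r = _raster([(0, 0, y, 10) for y in (1, 2)]
                    + [(1, 0, y, 10) for y in (1, 2)]
                    + [(0, 1, y, 10) for y in (1, 2)])
        assert spatial_cv(r, (0.5, 0.5), 5) == 0.0

    def test_spatial_cv_hand_computed(self):
        # cross-year means 8, 10, 12 -> sample SD 2, mean 10 -> 0.2
        r = _raster([(0, 0, 1, 8), (1, 0, 1, 10), (0, 1, 1, 12),
                     (0, 0, 2, 8), (1, 0, 2, 10), (0, 1, 2, 12)])
        assert spatial_cv(r, (0.5, 0.5), 5) == pytest.approx(0.2)

    def test_temporal_cv_single_cell_hand_computed(self):
        # years (9, 11): sample SD sqrt(2), mean 10; plus one constant cell
        r = _raster([(0, 0, 1, 9), (0, 0, 2, 11), (1, 0, 1, 10), (1, 0, 2, 10)])
        cv = temporal_cv(r, (0.0, 0.0), radius_km=0.5)  # only cell (0,0)
        assert cv == pytest.approx(np.sqrt(2.0) / 10.0)

    def test_temporal_cv_averages_cell_cvs(self):
        # cell A has CV 0.1, cell B has CV 0.3 -> mean 0.2
        a = 10.0
        sd_to_years = lambda m, cv: (m - m * cv / np.sqrt(2), m + m * cv / np.sqrt(2))
        ya = sd_to_years(a, 0.1)
        yb = sd_to_years(a, 0.3)
        r = _raster([(0, 0, 1, ya[0]), (0, 0, 2, ya[1]),
                     (1, 0, 1, yb[0]), (1, 0, 2, yb[1])])
        assert temporal_cv(r, (0.5, 0.0), 5) == pytest.approx(0.2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        cells = [(x, y, yr, rng.uniform(5, 15))
                 for x in range(3) for y in range(3) for yr in (1, 2, 3)]
        r = _raster(cells)
        r5 = r.assign(value=r["value"] * 5)
        assert spatial_cv(r, (1, 1), 5) == pytest.approx(spatial_cv(r5, (1, 1), 5))
        assert temporal_cv(r, (1, 1), 5) == pytest.approx(temporal_cv(r5, (1, 1), 5))

    def test_too_few_cells_raise(self):
        r = _raster([(0, 0, 1, 5), (0, 0, 2, 6)])
        with pytest.raises(ValueError):
            spatial_cv(r, (0, 0), 0.5)


class TestAssembleDesign:
    def test_centering_contract(self, small_dataset):
        ds = small_dataset
        obs = ds.make_group_cv_observations(seed=1)
        design = covariates.assemble_within_design(
            obs, ds.stations, ds.raster, ds.ranges
        )
        per_species = design.groupby("species")[covariates.WITHIN_COVARIATES].mean()
        assert np.abs(per_species.to_numpy()).max() < 1e-10

    def test_matches_generator_design(self, small_dataset):
        """Recomputed covariates equal the generator's recorded design."""
        ds = small_dataset
        obs = ds.make_group_cv_observations(seed=1)
        design = covariates.assemble_within_design(
            obs, ds.stations, ds.raster, ds.ranges
        )
        tg = ds.truth_groups()
        m = design.merge(tg, on=["species", "location_id"], suffixes=("", "_t"))
        for c in covariates.WITHIN_COVARIATES:
            assert np.allclose(m[c], m[f"{c}_t"], atol=1e-9)

    def test_cv_scaled_by_1000(self, small_dataset):
        ds = small_dataset
        obs = ds.make_group_cv_observations(seed=1)
        design = covariates.assemble_within_design(
            obs, ds.stations, ds.raster, ds.ranges
        )
        assert np.allclose(design["cv_hat"], obs["cv_hat"] * 1000)

    def test_missing_station_raises(self, small_dataset):
        ds = small_dataset
        obs = ds.make_group_cv_observations(seed=1)
        obs.loc[0, "location_id"] = "nowhere"
        with pytest.raises(ValueError, match="nowhere"):
            covariates.assemble_within_design(obs, ds.stations, ds.raster, ds.ranges)


class TestSpeciesProfiles:
    def test_centered_and_scaled(self, small_dataset):
        ds = small_dataset
        sp = ds.make_species_cv_observations(seed=2)
        prof = covariates.build_species_profiles(sp, ds.traits)
        Z = prof[covariates.AMONG_COVARIATES].to_numpy()
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)
        assert set(prof["mig_status"]) <= {0, 1}


class TestVif:
    def test_orthogonal_columns_unity(self):
        rng = np.random.default_rng(1)
        # columns orthonormal to each other and to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(50), rng.normal(size=(50, 3))]))
        assert np.allclose(vif(q[:, 1:]), 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        out = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_bivariate_closed_form(self):
        """Two columns with sample correlation 0.6: VIF = 1/(1-0.36)."""
        rng = np.random.default_rng(3)
        n = 2000
        a = rng.normal(size=n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=n)
        # force the sample correlation to be exactly 0.6 via Gram-Schmidt
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        resid = b - np.dot(a, b) / n * a
        b_exact = 0.6 * a + np.sqrt(1 - 0.36) * resid / resid.std()
        out = vif(np.column_stack([a, b_exact]))
        assert np.allclose(out, 1.5625, atol=1e-3)
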