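"""Range geometry, habitat extraction, occupancy upscaling, trend windows."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays
from shapely.geometry import MultiPoint, Polygon, box

from autoredlist.errors import GridMismatchError, UnknownCodeError
from autoredlist.grids import GridSpec, Raster
from autoredlist.habitat import (
    Crosswalk,
    LandCoverSeries,
    SpeciesProfile,
    build_esh,
    compute_eoo,
    criterion_window,
    esh_area,
    percent_change,
    trend_window,
    upscale_aoo,
)
from helpers import aoo_oracle, make_esh

KM = 1000.0


def profile_with(season_polygons, **kw):
    defaults = dict(
        species_id="sp",
        taxon_class="mammal",
        suitable_habitat_codes=frozenset({"1.6"}),
        body_mass_g=1000.0,
        generation_length_yr=5.0,
    )
    defaults.update(kw)
    return SpeciesProfile(season_polygons=season_polygons, **defaults)


class TestEoo:
    def test_right_triangle_area(self):
        tri = Polygon([(0, 0), (300 * KM, 0), (0, 400 * KM)])
        assert compute_eoo(profile_with({"resident": tri})) == pytest.approx(60000.0)

    def test_migratory_takes_smaller_hull(self):
        # breeding hull 1000 km², nonbreeding hull 600 km², no resident range
        breeding = box(0, 0, 40 * KM, 25 * KM)
        nonbreeding = box(100 * KM, 0, 130 * KM, 20 * KM)
        p = profile_with({"breeding": breeding, "nonbreeding": nonbreeding})
        assert compute_eoo(p) == pytest.approx(600.0)

    def test_hull_idempotent_on_nonconvex_range(self):
        l_shape = Polygon(
            [(0, 0), (30 * KM, 0), (30 * KM, 10 * KM), (10 * KM, 10 * KM),
             (10 * KM, 30 * KM), (0, 30 * KM)]
        )
        hull = l_shape.convex_hull
        assert compute_eoo(profile_with({"resident": l_shape})) == pytest.approx(
            compute_eoo(profile_with({"resident": hull}))
        )

    def test_invariant_to_interior_points_and_vertex_order(self):
        pts = [(0, 0), (50 * KM, 0), (50 * KM, 50 * KM), (0, 50 * KM)]
        base = MultiPoint(pts).convex_hull
        with_interior = MultiPoint(pts + [(10 * KM, 20 * KM), (30 * KM, 5 * KM)]).convex_hull
        reordered = MultiPoint(list(reversed(pts))).convex_hull
        ref = compute_eoo(profile_with({"resident": base}))
        assert compute_eoo(profile_with({"resident": with_interior})) == pytest.approx(ref)
        assert compute_eoo(profile_with({"resident": reordered})) == pytest.approx(ref)

    def test_degenerate_geometry_warns_and_returns_zero(self):
        line = shapely.LineString([(0, 0), (10 * KM, 0)])
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_eoo(profile_with({"resident": line})) == 0.0


def tiny_series(codes, years=(2000,), cell_size=300.0, legend=(1, 2)):
    codes = np.asarray(codes, dtype=np.int16)
    if codes.ndim == 2:
        codes = np.broadcast_to(codes, (len(years),) + codes.shape).copy()
    grid = GridSpec(rows=codes.shape[1], cols=codes.shape[2], cell_size=cell_size)
    return LandCoverSeries(
        grid=grid, years=years, data=codes, legend=frozenset(legend)
    )


XWALK = Crosswalk({1: {"1.6"}, 2: {"14.1"}})


class TestBuildEsh:
    def setup_method(self):
        self.codes = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 2]])
        self.lc = tiny_series(self.codes)
        self.whole = box(0, 0, 900, 900)

    def test_forest_cells_inside_range_counted(self):
        p = profile_with({"resident": self.whole})
        esh = build_esh(p, self.lc, XWALK)
        assert int(esh.mask(2000).sum()) == 4

    def test_altitude_band_excludes_cells(self):
        # gradient DEM: top row 0 m, bottom row 200 m; cap at 150 m drops the
        # bottom-left forest cell
        dem = Raster(
            grid=self.lc.grid,
            values=np.array([[0.0] * 3, [100.0] * 3, [200.0] * 3]),
        )
        p = profile_with({"resident": self.whole}, altitude_min_m=0.0, altitude_max_m=150.0)
        esh = build_esh(p, self.lc, XWALK, dem)
        assert int(esh.mask(2000).sum()) == 3

    def test_unmatched_habitat_codes_set_empty_flag(self):
        p = profile_with({"resident": self.whole},
                         suitable_habitat_codes=frozenset({"9.9"}))
        esh = build_esh(p, self.lc, XWALK)
        assert esh.empty_flag

    def test_grid_mismatch_rejected(self):
        dem = Raster(grid=GridSpec(rows=3, cols=3, cell_size=500.0),
                     values=np.zeros((3, 3)))
        with pytest.raises(GridMismatchError):
            build_esh(profile_with({"resident": self.whole}), self.lc, XWALK, dem)

    def test_unknown_landcover_code_rejected(self):
        lc = tiny_series(np.array([[1, 2, 7], [2, 1, 2], [1, 2, 2]]))
        with pytest.raises(UnknownCodeError, match="7"):
            build_esh(profile_with({"resident": self.whole}), lc, XWALK)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_cell_conjunction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = cols = int(rng.integers(10, 51))
        cell = 300.0
        codes = rng.integers(1, 3, size=(rows, cols)).astype(np.int16)
        lc = tiny_series(codes, cell_size=cell)
        pts = rng.uniform(0, [cols * cell, rows * cell], size=(6, 2))
        poly = MultiPoint(pts.tolist()).convex_hull.buffer(2 * cell)
        dem = Raster(grid=lc.grid, values=rng.uniform(0, 1000, size=(rows, cols)))
        p = profile_with({"resident": poly}, altitude_min_m=100.0, altitude_max_m=800.0)
        esh = build_esh(p, lc, XWALK, dem)

        expected = np.zeros((rows, cols), dtype=bool)
        for r in range(rows):
            for c in range(cols):
                x = (c + 0.5) * cell
                y = (rows - r - 0.5) * cell
                expected[r, c] = (
                    poly.contains(shapely.Point(x, y))
                    and codes[r, c] == 1
                    and 100.0 <= dem.values[r, c] <= 800.0
                )
        assert np.array_equal(esh.mask(2000), expected)


class TestAreas:
    def test_esh_area_is_count_times_cell_area(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask.flat[:10] = True
        assert esh_area(make_esh(mask, cell_size=300.0), 2000) == pytest.approx(0.9)
        assert esh_area(make_esh(np.zeros((5, 5), bool)), 2000) == 0.0
        big = np.zeros((40, 25), dtype=bool)
        big[:] = True
        assert esh_area(make_esh(big, cell_size=1000.0), 2000) == pytest.approx(1000.0)

    def test_single_fine_cell_occupies_one_coarse_cell(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 7] = True
        assert upscale_aoo(make_esh(mask, cell_size=300.0), 2000) == pytest.approx(4.0)

    def test_same_coarse_cell_not_double_counted(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[9, 0] = True
        mask[9, 1] = True  # both centers in the coarse cell anchored at the origin
        assert upscale_aoo(make_esh(mask, cell_size=300.0), 2000) == pytest.approx(4.0)

    def test_three_distinct_coarse_cells(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[9, 0] = True
        mask[9, 10] = True
        mask[9, 20] = True  # 300-m columns 0/10/20 → 2-km columns 0/1/3
        assert upscale_aoo(make_esh(mask, cell_size=300.0), 2000) == pytest.approx(12.0)

    @given(
        arrays(bool, (23, 31)),
        st.sampled_from([300.0, 500.0, 1000.0]),
    )
    def test_aoo_matches_membership_oracle_and_bounds(self, mask, cell):
        esh = make_esh(mask, cell_size=cell)
        aoo = upscale_aoo(esh, 2000, coarse_cell_size=2000.0)
        assert aoo == pytest.approx(aoo_oracle(mask, cell, 2000.0))
        area = esh_area(esh, 2000)
        assert aoo >= area or mask.sum() == 0
        assert aoo <= mask.sum() * 4.0

    def test_removing_cells_never_increases_area_or_aoo(self, rng):
        mask = rng.random((30, 30)) < 0.4
        esh = make_esh(mask)
        a0, o0 = esh_area(esh, 2000), upscale_aoo(esh, 2000)
        reduced = mask.copy()
        on = np.flatnonzero(reduced)
        reduced.flat[rng.choice(on, size=len(on) // 3, replace=False)] = False
        esh2 = make_esh(reduced)
        assert esh_area(esh2, 2000) <= a0
        assert upscale_aoo(esh2, 2000) <= o0

    def test_coarse_smaller_than_fine_rejected(self):
        mask = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError):
            upscale_aoo(make_esh(mask, cell_size=300.0), 2000, coarse_cell_size=100.0)


class TestTrendWindows:
    @pytest.mark.parametrize(
        "gl,start,factor",
        [(2.0, 2005, 1.0), (5.0, 2000, 1.0), (8.0, 1992, 1.0), (12.0, 1992, 1.5)],
    )
    def test_window_start_and_scale(self, gl, start, factor):
        assert trend_window(gl, 1992, 2015) == (start, pytest.approx(factor))

    def test_nonpositive_generation_length_rejected(self):
        with pytest.raises(ValueError):
            trend_window(0.0, 1992, 2015)

    def test_c1_windows_use_their_own_floors(self):
        # CR window: max(3 yr, 1 GL) with GL 5 → 5 trailing years
        assert criterion_window(3, 1, 5.0, 1992, 2015) == (2010, 1.0)
        # VU window: max(10 yr, 3 GL) with GL 12 → 36 yr, longer than the span
        start, f = criterion_window(10, 3, 12.0, 1992, 2015)
        assert (start, f) == (1992, pytest.approx(1.5))

    def test_percent_change_examples(self):
        series = {2005: 100.0, 2015: 60.0}
        assert percent_change(series, 2005, 2015, 1.0) == pytest.approx(-40.0)
        assert percent_change(series, 2005, 2015, 1.5) == pytest.approx(-60.0)
        flat = {2005: 7.0, 2015: 7.0}
        assert percent_change(flat, 2005, 2015, 3.0) == 0.0

    def test_zero_baseline_is_flagged_undefined(self):
        assert math.isnan(percent_change({2005: 0.0, 2015: 3.0}, 2005, 2015))

    def test_missing_year_rejected(self):
        with pytest.raises(KeyError):
            percent_change({2005: 1.0}, 2005, 2015)
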