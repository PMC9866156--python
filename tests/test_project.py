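"""Scenario projection, spherical-area accounting, change maps and
centroid shifts."""

import numpy as np
import pytest

import nichekit as nk
from nichekit.project import area_by_class, centroid, change, project, shift
from nichekit.raster import EnvStack, cell_area_km2


def grid_stack(nrow=10, ncol=10, y_origin=10.0, cell=1.0):
    return EnvStack(
        layers={"a": np.zeros((nrow, ncol))}, x_origin=0.0, y_origin=y_origin, cell_size=cell
    )


class TestProject:
    def test_constant_stack_gives_constant_map(self, small_fit, landscape):
        _, _, em = small_fit
        const = EnvStack(
            layers={n: np.zeros((5, 5)) for n in em.variables},
            cell_size=landscape.cell_size,
        )
        smap = project(em, const)
        assert np.unique(smap.p).size == 1

    def test_nodata_propagates(self, small_fit, landscape):
        _, _, em = small_fit
        layers = {n: landscape.layers[n].copy() for n in landscape.names}
        layers[em.variables[0]][0, 0] = landscape.nodata
        holey = EnvStack(layers=layers, x_origin=landscape.x_origin,
                         y_origin=landscape.y_origin, cell_size=landscape.cell_size)
        smap = project(em, holey)
        assert np.isnan(smap.p[0, 0])
        assert np.isfinite(smap.p[1:, :]).all()

    def test_presence_cells_score_higher_than_random(self, small_fit, landscape, species):
        _, _, em = small_fit
        smap = project(em, landscape)
        surf = nk.suitability_surface(species, landscape)
        occ = nk.sample_occurrences(surf, landscape, 200, seed=77)
        row, col = landscape.point_to_rowcol(occ.lon, occ.lat)
        assert smap.p[row, col].mean() > np.nanmean(smap.p)

    def test_missing_layer_named(self, small_fit):
        _, _, em = small_fit
        bad = EnvStack(layers={"only": np.zeros((4, 4))})
        with pytest.raises(ValueError, match=em.variables[0]):
            project(em, bad)


class TestAreas:
    def test_areas_sum_to_total_valid_area(self):
        stack = grid_stack(20, 20, y_origin=40.0)
        rng = np.random.default_rng(0)
        cls = rng.integers(0, 4, size=(20, 20))
        areas = area_by_class(cls, stack)
        total = stack.cell_areas_km2().sum()
        assert abs(sum(areas.values()) - total) / total < 1e-9

    def test_empty_class_absent(self):
        stack = grid_stack(4, 4)
        cls = np.zeros((4, 4), dtype=int)
        areas = area_by_class(cls, stack)
        assert areas.get(1, 0.0) == 0.0
        assert areas[0] == pytest.approx(stack.cell_areas_km2().sum())


class TestChange:
    def test_identical_maps_no_change(self):
        stack = grid_stack()
        b = np.zeros((10, 10))
        b[3:6, 3:6] = 1
        ch = change(b, b, stack)
        assert ch.gain_km2 == 0.0 and ch.loss_km2 == 0.0

    def test_complement_swaps_areas(self):
        stack = grid_stack()
        b = np.zeros((10, 10))
        b[:5] = 1
        ch = change(b, 1 - b, stack)
        areas = stack.cell_areas_km2()
        assert ch.gain_km2 == pytest.approx(areas[b == 0].sum())
        assert ch.loss_km2 == pytest.approx(areas[b == 1].sum())

    def test_single_flipped_cell_gain(self):
        stack = grid_stack(y_origin=5.0)
        now = np.zeros((10, 10))
        fut = now.copy()
        fut[2, 7] = 1
        ch = change(now, fut, stack)
        lat_top = 5.0 - 2 * 1.0
        assert ch.gain_km2 == pytest.approx(cell_area_km2(lat_top - 1, lat_top, 1.0))

    def test_gain_minus_loss_identity(self):
        stack = grid_stack(15, 15, y_origin=60.0)
        rng = np.random.default_rng(3)
        now = rng.integers(0, 2, (15, 15)).astype(float)
        fut = rng.integers(0, 2, (15, 15)).astype(float)
        ch = change(now, fut, stack)
        areas = stack.cell_areas_km2()
        diff = areas[fut == 1].sum() - areas[now == 1].sum()
        assert ch.gain_km2 - ch.loss_km2 == pytest.approx(diff, abs=1e-9)

    def test_geometry_mismatch(self):
        stack = grid_stack()
        with pytest.raises(ValueError, match="geometry"):
            change(np.zeros((10, 10)), np.zeros((9, 10)), stack)


class TestCentroid:
    def test_symmetric_mask_centers(self):
        # suitable block symmetric about (10 E, 20 S): longitude is exact;
        # latitude agrees to the (tiny) spherical-weighting asymmetry
        stack = EnvStack(layers={"a": np.zeros((50, 50))}, x_origin=0.0,
                         y_origin=0.0, cell_size=0.5)
        b = np.zeros((50, 50))
        b[36:44, 16:24] = 1  # lat centers -18.25..-21.75, lon centers 8.25..11.75
        c = centroid(b, stack)
        assert c.lon == pytest.approx(10.0, abs=1e-9)
        assert c.lat == pytest.approx(-20.0, abs=0.01)

    def test_single_cell(self):
        stack = grid_stack(y_origin=5.0)
        b = np.zeros((10, 10))
        b[4, 6] = 1
        c = centroid(b, stack)
        lon, lat = stack.cell_center(np.array([4]), np.array([6]))
        assert (c.lon, c.lat) == (lon[0], lat[0])

    def test_two_cells_symmetric_in_sin_latitude(self):
        # two cells at equal |latitude| have equal spherical area; centroid
        # lies exactly between their centers
        stack = grid_stack(nrow=41, y_origin=20.5)
        b = np.zeros((41, 10))
        b[0, 3] = 1   # lat center 20
        b[40, 3] = 1  # lat center -20
        c = centroid(b, stack)
        assert c.lat == pytest.approx(0.0, abs=1e-9)

    def test_area_weighting_pulls_toward_equator(self):
        # cells at 10 and 30 degrees: the 10-degree cell is larger, so the
        # weighted latitude is below the arithmetic midpoint 20
        stack = grid_stack(nrow=31, y_origin=30.5)
        b = np.zeros((31, 10))
        b[0, 0] = 1   # lat 30
        b[20, 0] = 1  # lat 10
        c = centroid(b, stack)
        w30 = cell_area_km2(29.5, 30.5, 1.0)
        w10 = cell_area_km2(9.5, 10.5, 1.0)
        assert c.lat == pytest.approx((30 * w30 + 10 * w10) / (w30 + w10))
        assert c.lat < 20.0

    def test_invariant_to_unsuitable_relabeling(self):
        stack = grid_stack(y_origin=8.0)
        b = np.zeros((10, 10))
        b[2:4, 2:4] = 1
        c1 = centroid(b, stack)
        b2 = b.copy()
        b2[b2 == 0] = 0.0  # relabel no-op; also compare with nodata mixed in
        b2[9, 9] = np.nan
        c2 = centroid(b2, stack)
        assert (c1.lon, c1.lat) == (c2.lon, c2.lat)

    def test_no_suitable_cells(self):
        with pytest.raises(ValueError, match="no suitable"):
            centroid(np.zeros((5, 5)), grid_stack(5, 5))

    def test_antimeridian_straddle_rejected(self):
        stack = EnvStack(layers={"a": np.zeros((2, 360))}, x_origin=-180.0,
                         y_origin=1.0, cell_size=1.0)
        b = np.zeros((2, 360))
        b[0, 0] = 1
        b[0, 359] = 1
        with pytest.raises(ValueError, match="antimeridian"):
            centroid(b, stack)


def test_shift_distance_and_bearing():
    from nichekit.project import Centroid

    a = Centroid(lon=0.0, lat=0.0)
    b = Centroid(lon=0.0, lat=10.0)
    out = shift(a, b)
    assert out["bearing_deg"] == pytest.approx(0.0)
    assert out["distance_km"] == pytest.approx(6371.0 * np.radians(10), rel=1e-6)
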