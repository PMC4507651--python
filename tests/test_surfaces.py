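"""IDW gridding, DEM construction and bilinear sampling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canoheight as ch
from canoheight.core import PointCloud, RasterGrid, GROUND
from canoheight.surfaces import grid_for_bounds


class TestIDW:
    def test_constant_field_everywhere(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        grid = grid_for_bounds((0, 0, 10, 10), 1.0)
        out = ch.idw_interpolate((x, y, np.full(50, 7.0)), grid)
        covered = np.isfinite(out.values)
        assert covered.any()
        np.testing.assert_allclose(out.values[covered], 7.0)

    def test_single_point_cell_and_radius(self):
        grid = grid_for_bounds((0, 0, 30, 30), 1.0)
        out = ch.idw_interpolate(([15.0], [15.0], [42.0]), grid,
                                 ch.IDWParams(max_radius=3.0))
        xs, ys = out.cell_centers()
        c = np.argmin(np.abs(xs - 15.0))
        r = np.argmin(np.abs(ys - 15.0))
        assert out.values[r, c] == pytest.approx(42.0)
        assert np.isnan(out.values[0, 0])  # beyond the search radius

    def test_two_equidistant_points_average(self):
        # cell centre at (1,0): points at (0,0) and (2,0) are equidistant
        grid = RasterGrid((0.0, 0.0), 1.0, np.full((1, 3), np.nan))
        out = ch.idw_interpolate(([0.0, 2.0], [0.0, 0.0], [0.0, 10.0]), grid)
        assert out.values[0, 1] == pytest.approx(5.0)

    def test_empty_input_rejected(self):
        grid = grid_for_bounds((0, 0, 1, 1), 1.0)
        with pytest.raises(ValueError, match="no input"):
            ch.idw_interpolate(([], [], []), grid)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_bounded_by_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 40)
        x, y = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
        z = rng.uniform(-5, 25, n)
        grid = grid_for_bounds((0, 0, 10, 10), 1.0)
        out = ch.idw_interpolate((x, y, z), grid)
        covered = np.isfinite(out.values)
        assert np.all(out.values[covered] >= z.min() - 1e-12)
        assert np.all(out.values[covered] <= z.max() + 1e-12)


class TestBuildDEM:
    def test_planar_ground_reproduced(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 20, 3000), rng.uniform(0, 20, 3000)
        z = 0.5 * x - 0.2 * y + 3.0
        cloud = PointCloud(x, y, z, classification=np.full(3000, GROUND))
        dem = ch.build_dem(cloud, cell=0.3)
        xs, ys = dem.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        err = dem.values - (0.5 * gx - 0.2 * gy + 3.0)
        assert np.sqrt(np.nanmean(err ** 2)) < 0.02

    def test_flat_ground_constant(self):
        rng = np.random.default_rng(3)
        cloud = PointCloud(rng.uniform(0, 10, 500), rng.uniform(0, 10, 500),
                           np.full(500, 100.0),
                           classification=np.full(500, GROUND))
        dem = ch.build_dem(cloud)
        np.testing.assert_allclose(
            dem.values[np.isfinite(dem.values)], 100.0, atol=1e-9)

    def test_cell_size_honoured(self):
        rng = np.random.default_rng(4)
        cloud = PointCloud(rng.uniform(0, 10, 200), rng.uniform(0, 10, 200),
                           np.zeros(200), classification=np.full(200, GROUND))
        dem = ch.build_dem(cloud, cell=0.5)
        assert dem.cell == 0.5

    def test_requires_ground_points(self):
        cloud = PointCloud([0, 1], [0, 1], [0, 1])
        with pytest.raises(ValueError, match="ground"):
            ch.build_dem(cloud)


class TestSampleSurface:
    def test_constant_grid(self):
        grid = RasterGrid((0, 0), 1.0, np.full((5, 5), 3.3))
        assert ch.sample_surface(grid, 1.7, 2.9) == pytest.approx(3.3)

    def test_bilinear_reproduces_plane(self):
        xs = np.arange(6) * 1.0
        gx, gy = np.meshgrid(xs, xs)
        grid = RasterGrid((0, 0), 1.0, 2.0 * gx - 0.7 * gy + 1.0)
        for x, y in [(0.3, 0.4), (2.5, 4.1), (4.99, 0.01)]:
            assert ch.sample_surface(grid, x, y) == pytest.approx(
                2.0 * x - 0.7 * y + 1.0, abs=1e-9)

    def test_exact_cell_centre(self):
        rng = np.random.default_rng(5)
        grid = RasterGrid((0, 0), 0.5, rng.uniform(0, 1, (4, 4)))
        assert ch.sample_surface(grid, 1.0, 1.5) == pytest.approx(
            grid.values[3, 2])

    def test_outside_extent_raises(self):
        grid = RasterGrid((0, 0), 1.0, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="outside"):
            ch.sample_surface(grid, 10.0, 1.0)

    def test_nodata_neighbourhood_raises(self):
        vals = np.full((3, 3), np.nan)
        grid = RasterGrid((0, 0), 1.0, vals)
        with pytest.raises(ValueError, match="nodata"):
            ch.sample_surface(grid, 1.0, 1.0)

    def test_partial_nodata_uses_remaining_corners(self):
        vals = np.array([[1.0, np.nan], [1.0, 1.0]])
        grid = RasterGrid((0, 0), 1.0, vals)
        assert ch.sample_surface(grid, 0.5, 0.5) == pytest.approx(1.0)


class TestNormalizeAndCHM:
    def test_normalization_invertible(self):
        rng = np.random.default_rng(6)
        x, y = rng.uniform(0, 10, 300), rng.uniform(0, 10, 300)
        z = 0.2 * x + 5.0 + rng.uniform(0, 20, 300)
        cloud = PointCloud(x, y, z)
        xs = np.arange(-1, 13) * 1.0
        gxx, gyy = np.meshgrid(xs, xs)
        dem = ch.RasterGrid((-1.0, -1.0), 1.0, 0.2 * gxx + 5.0)
        h = ch.conventional_normalize(cloud, dem)
        np.testing.assert_allclose(
            h + ch.sample_surface(dem, x, y), z, atol=1e-12)

    def test_ground_heights_near_zero_on_plane(self):
        rng = np.random.default_rng(7)
        x, y = rng.uniform(0, 20, 2000), rng.uniform(0, 20, 2000)
        z = 0.4 * x + 0.1 * y
        cloud = PointCloud(x, y, z, classification=np.full(2000, GROUND))
        dem = ch.build_dem(cloud)
        h = ch.conventional_normalize(cloud, dem)
        assert np.abs(h).max() < 0.02

    def test_chm_constant_heights(self):
        rng = np.random.default_rng(8)
        x, y = rng.uniform(0, 10, 200), rng.uniform(0, 10, 200)
        chm = ch.build_chm(x, y, np.full(200, 12.0), cell=0.5)
        covered = np.isfinite(chm.values)
        np.testing.assert_allclose(chm.values[covered], 12.0)

    def test_chm_empty_rejected(self):
        with pytest.raises(ValueError):
            ch.build_chm([], [], [])

    def test_difference_raster_alignment_and_nodata(self):
        a = ch.RasterGrid((0, 0), 1.0, np.array([[1.0, np.nan], [2.0, 3.0]]))
        b = ch.RasterGrid((0, 0), 1.0, np.array([[0.5, 1.0], [np.nan, 1.0]]))
        d = ch.difference_raster(a, b)
        assert d.values[0, 0] == pytest.approx(0.5)
        assert np.isnan(d.values[0, 1]) and np.isnan(d.values[1, 0])
        assert d.values[1, 1] == pytest.approx(2.0)
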