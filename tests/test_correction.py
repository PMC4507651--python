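"""Per-tree correction: grouping, gravity centre, rigid renormalization."""

import math
import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

import canoheight as ch
from canoheight.core import PointCloud, RasterGrid, CrownSet, VEGETATION
from canoheight.correction import DegenerateGroupError, TreeGroup


def _flat_dem(level=0.0, lo=-10.0, hi=30.0, cell=1.0):
    n = int((hi - lo) / cell) + 1
    return RasterGrid((lo, lo), cell, np.full((n, n), level))


def _veg_cloud(x, y, z):
    n = len(x)
    return PointCloud(x, y, z, np.ones(n, int), np.full(n, VEGETATION))


def _square(x0, y0, side):
    return Polygon([(x0, y0), (x0 + side, y0),
                    (x0 + side, y0 + side), (x0, y0 + side)])


class TestGroupByCrown:
    def test_containment_split(self):
        x = np.array([1, 2, 3, 4, 4.5, 10, 11, 12.0])
        y = np.full(8, 2.5)
        cloud = _veg_cloud(x, y, np.full(8, 5.0))
        crowns = CrownSet([(0, _square(0, 0, 5))])
        groups, gap = ch.group_by_crown(cloud, crowns)
        assert groups[0].n == 5
        assert gap.size == 3

    def test_overlap_goes_to_lowest_id(self):
        cloud = _veg_cloud([2.5], [2.5], [5.0])
        crowns = CrownSet([(3, _square(0, 0, 5)), (1, _square(1, 1, 5))])
        groups, _ = ch.group_by_crown(cloud, crowns)
        by_id = {g.crown_id: g.n for g in groups}
        assert by_id[1] == 1 and by_id[3] == 0

    def test_truth_polygons_recover_tree_membership(self, slope30_run):
        run = slope30_run
        truth = run.truth
        total = correct = 0
        for g in run.result.groups:
            want = int(g.crown_id)
            got = truth.tree_id[g.indices]
            total += g.n
            correct += int((got == want).sum())
        assert total > 0
        assert correct / total >= 0.98

    def test_empty_crownset_rejected(self):
        cloud = _veg_cloud([0.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="empty"):
            ch.group_by_crown(cloud, CrownSet([]))


class TestGravityCentre:
    def test_single_point_is_itself(self):
        cloud = _veg_cloud([3.0], [4.0], [7.0])
        assert ch.gravity_centre(cloud, np.array([0]), _flat_dem()) == \
            pytest.approx((3.0, 4.0))

    def test_symmetric_points_balance(self):
        cloud = _veg_cloud([-2.0, 2.0], [1.0, 1.0], [6.0, 6.0])
        gx, gy = ch.gravity_centre(cloud, np.arange(2), _flat_dem())
        assert gx == pytest.approx(0.0, abs=1e-12)
        assert gy == pytest.approx(1.0)

    def test_weighted_mean_direct_evaluation(self):
        # weights (1, 1, 2) over flat DEM at 0 -> x_ig = (0+2+8)/4 = 2.5
        cloud = _veg_cloud([0.0, 2.0, 4.0], [0.0, 0.0, 0.0], [1.0, 1.0, 2.0])
        gx, _ = ch.gravity_centre(cloud, np.arange(3), _flat_dem())
        assert gx == pytest.approx(2.5)

    def test_all_below_ground_degenerate(self):
        cloud = _veg_cloud([1.0, 2.0], [1.0, 1.0], [-3.0, -3.0])
        with pytest.raises(DegenerateGroupError):
            ch.gravity_centre(cloud, np.arange(2), _flat_dem(level=0.0))


class TestCorrectGroup:
    def test_flat_dem_returns_raw_z(self):
        cloud = _veg_cloud([1, 2, 3.0], [1, 1, 1.0], [4.0, 9.0, 6.0])
        g = TreeGroup(crown_id=0, indices=np.arange(3))
        out = ch.correct_group(cloud, g, _flat_dem(level=0.0))
        np.testing.assert_allclose(out.corrected_heights, cloud.z)
        assert out.base_elevation == pytest.approx(0.0)

    def test_rigid_shift_preserves_range(self):
        rng = np.random.default_rng(0)
        cloud = _veg_cloud(rng.uniform(0, 5, 40), rng.uniform(0, 5, 40),
                           rng.uniform(2, 15, 40))
        g = ch.correct_group(cloud, TreeGroup(0, np.arange(40)),
                             _flat_dem(level=3.0))
        assert (g.corrected_heights.max() - g.corrected_heights.min()) == \
            pytest.approx(cloud.z.max() - cloud.z.min(), abs=1e-12)

    def test_sloped_scene_apex_recovery_beats_conventional(self, slope30_run):
        """Corrected apex heights land near truth; conventional estimates
        carry the slope bias."""
        he = slope30_run.height_errors()
        assert np.abs(he.corrected_error_m).max() < 0.15
        assert (he.conventional_error_m > np.abs(he.corrected_error_m)).any()


class TestCorrectScene:
    def test_flat_scene_is_noop(self, flat_run):
        r = flat_run.result
        assert np.abs(r.corrected - r.conventional).max() < 1e-6

    def test_crown_edge_span_at_study_geometry(self):
        """A 6 m crown on a 38.2-degree slope spans roughly +-2.2 m of
        corrected-minus-conventional difference at the crown edges."""
        from canoheight.synthetic import SceneSpec, TreeSpec
        tree = TreeSpec((15.0, 15.0), height=24.4, crown_diameter=6.0,
                        crown_base_height=8.0)
        spec = SceneSpec(extent=(30, 30), slope_deg=38.2, trees=[tree],
                         noise_sd_z=0.0, seed=13)
        run = ch.run_scene(spec)
        diff = run.result.corrected - run.result.conventional
        expected = 3.0 * math.tan(math.radians(38.2))  # 2.36 m
        assert diff.max() == pytest.approx(expected, abs=0.4)
        assert diff.min() == pytest.approx(-expected, abs=0.4)

    def test_sign_alternates_across_trunk_along_slope(self, slope30_run):
        """Conventional normalization depresses the upslope half of each
        crown and elevates the downslope half, so the correction adds
        height upslope of the gravity centre and removes it downslope."""
        run = slope30_run
        for g in run.result.groups:
            if g.corrected_heights is None:
                continue
            conv = ch.conventional_normalize(run.cloud, run.dem)[g.indices]
            diff = g.corrected_heights - conv
            up = run.cloud.y[g.indices] > g.gravity_xy[1]  # aspect 0: +y up
            assert np.all(diff[up] > 0)
            assert np.all(diff[~up] < 0)

    def test_gap_points_thresholded(self):
        rng = np.random.default_rng(1)
        n = 60
        x = rng.uniform(0, 20, n)
        y = rng.uniform(0, 20, n)
        z = np.where(np.arange(n) % 2 == 0, 0.5, 6.0)  # shrub vs canopy
        cloud = _veg_cloud(x, y, z)
        crowns = CrownSet([(0, _square(100, 100, 2))])  # nothing inside
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(DegenerateGroupError):
                # all groups empty -> nothing correctable
                ch.correct_scene(cloud, crowns, _flat_dem(hi=110.0))

    def test_zero_crowns_rejected(self):
        cloud = _veg_cloud([1.0], [1.0], [5.0])
        with pytest.raises(ValueError):
            ch.correct_scene(cloud, CrownSet([]), _flat_dem())

    def test_tree_table_shape(self, flat_run):
        table = flat_run.result.tree_table()
        assert set(table.columns) >= {"crown_id", "x_ig", "y_ig", "z_ig",
                                      "n", "max_corrected_height"}
        assert len(table) == len(flat_run.result.groups)
        assert (table.n >= 1).all()
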