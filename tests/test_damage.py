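"""Damaged-streamline selection, count/distance volumes, averaging."""

import numpy as np
import pytest

from tractolesion.damage import (
    DamageModel,
    LesionMask,
    average_models,
    count_volume,
    distance_volume,
    select_damaged_streamlines,
    standardize_hemisphere,
)
from tractolesion.grids import GridMismatchError, VolumeGrid, VolumeImage
from tractolesion.io import Tractogram

from conftest import (
    mask_image,
    oracle_polyline_distances,
    oracle_select,
    random_tractogram,
    straight_streamline,
)


def lesion_at(grid, voxels, side="right"):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # side/centroid checks not under test
        return LesionMask(mask_image(grid, voxels), side)


class TestSelection:
    def test_all_zero_mask_selects_nothing(self, unit_grid):
        t = random_tractogram(unit_grid, np.random.default_rng(0), 10)
        empty = mask_image(unit_grid, [])
        assert len(select_damaged_streamlines(t, empty)) == 0

    def test_full_mask_selects_everything(self, unit_grid):
        t = random_tractogram(unit_grid, np.random.default_rng(1), 15)
        full = VolumeImage(unit_grid, np.ones(unit_grid.dims, dtype=np.uint8))
        assert list(select_damaged_streamlines(t, full)) == list(range(15))

    def test_single_crossing_streamline(self, unit_grid):
        crossing = straight_streamline([0, 5, 5], [1, 0, 0], 10)  # passes (5,5,5)
        clear1 = straight_streamline([0, 1, 1], [1, 0, 0], 10)
        clear2 = straight_streamline([0, 8, 8], [1, 0, 0], 10)
        t = Tractogram([clear1, crossing, clear2], unit_grid)
        lesion = lesion_at(unit_grid, [(5, 5, 5)])
        sel = select_damaged_streamlines(t, lesion)
        assert list(sel) == [1]
        assert oracle_select(t, np.asarray(lesion.volume.data)) == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, unit_grid, seed):
        rng = np.random.default_rng(seed)
        t = random_tractogram(unit_grid, rng, 60)
        vox = [tuple(v) for v in rng.integers(0, 10, size=(6, 3))]
        lesion = lesion_at(unit_grid, vox)
        got = list(select_damaged_streamlines(t, lesion))
        assert got == oracle_select(t, np.asarray(lesion.volume.data))

    def test_grid_mismatch(self, unit_grid):
        t = random_tractogram(unit_grid, np.random.default_rng(0), 3)
        other = VolumeGrid((10, 10, 10), np.diag([2.0, 1, 1, 1]))
        with pytest.raises(GridMismatchError):
            select_damaged_streamlines(t, lesion_at(other, [(1, 1, 1)]))


class TestCountVolume:
    def test_empty_selection(self, unit_grid):
        t = random_tractogram(unit_grid, np.random.default_rng(0), 5)
        cnt = count_volume(t, [])
        assert not np.asarray(cnt.data).any()

    def test_straight_line_five_voxels(self, unit_grid):
        s = straight_streamline([2, 3, 3], [1, 0, 0], 5)  # voxels (2..6, 3, 3)
        cnt = np.asarray(count_volume(Tractogram([s], unit_grid), [0]).data)
        assert cnt.sum() == 5
        for x in range(2, 7):
            assert cnt[x, 3, 3] == 1

    def test_distinct_streamline_counting(self, unit_grid):
        pts = np.full((10, 3), 4.0) + np.random.default_rng(0).uniform(-0.3, 0.3, (10, 3))
        cnt = np.asarray(count_volume(Tractogram([pts], unit_grid), [0]).data)
        assert cnt[4, 4, 4] == 1
        assert cnt.sum() == 1

    def test_sum_at_least_n_selected(self, unit_grid):
        t = random_tractogram(unit_grid, np.random.default_rng(3), 30)
        sel = list(range(30))
        assert np.asarray(count_volume(t, sel).data).sum() >= 30


class TestDistanceVolume:
    def test_zero_inside_lesion(self, unit_grid):
        s = straight_streamline([1, 5, 5], [1, 0, 0], 8)
        t = Tractogram([s], unit_grid)
        lesion = lesion_at(unit_grid, [(3, 5, 5)])
        d = np.asarray(distance_volume(t, [0], lesion).data)
        assert d[3, 5, 5] == 0.0

    def test_ten_mm_along_polyline(self, mm2_grid):
        # 1-mm steps from world (-13,-13,-13) along x; lesion voxel at start
        s = straight_streamline([-13, -13, -13], [1, 0, 0], 24)
        t = Tractogram([s], mm2_grid)
        lesion = lesion_at(mm2_grid, [(1, 1, 1)], side="left")  # world (-13,-13,-13)
        d = np.asarray(distance_volume(t, [0], lesion).data)
        # the point 10 mm along sits at world x = -3 -> voxel x index 6;
        # that voxel also contains the point at 9 mm -> min rule gives 9
        vox = mm2_grid.world_to_voxel(np.array([-3.0, -13.0, -13.0]))
        per_point = oracle_polyline_distances(
            s, np.array([True] + [False] * 23)
        )
        assert d[tuple(vox)] == min(per_point[9], per_point[10])

    def test_mean_over_streamlines(self, unit_grid):
        # two streamlines meet in voxel (5,5,5) with lesion distances 4 and 6
        a = straight_streamline([1, 5, 5], [1, 0, 0], 6)  # lesion at (1,5,5), d=4
        b = straight_streamline([5, 0, 5], [0, 1, 0], 7)  # passes (5,5,5) at arc 5
        lesion = lesion_at(unit_grid, [(1, 5, 5), (5, 6, 5)])
        # a: point (5,5,5) is 4 mm from lesion point (1,5,5)
        # b: point (5,5,5) is arc 5, nearest lesion point (5,6,5) at arc 6 -> d=1
        t = Tractogram([a, b], unit_grid)
        d = np.asarray(distance_volume(t, [0, 1], lesion).data)
        assert d[5, 5, 5] == pytest.approx((4.0 + 1.0) / 2)

    def test_nan_where_untraversed(self, unit_grid):
        s = straight_streamline([1, 5, 5], [1, 0, 0], 4)
        t = Tractogram([s], unit_grid)
        d = np.asarray(distance_volume(t, [0], lesion_at(unit_grid, [(1, 5, 5)])).data)
        assert np.isnan(d[9, 9, 9])

    def test_unselected_streamline_without_lesion_point_errors(self, unit_grid):
        s = straight_streamline([1, 1, 1], [1, 0, 0], 4)
        t = Tractogram([s], unit_grid)
        with pytest.raises(ValueError, match="no lesion-interior point"):
            distance_volume(t, [0], lesion_at(unit_grid, [(9, 9, 9)]))

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_under_point_order_reversal(self, unit_grid, seed):
        rng = np.random.default_rng(seed)
        t = random_tractogram(unit_grid, rng, 40)
        block = [(x, y, z) for x in range(3, 7) for y in range(3, 7) for z in range(3, 7)]
        lesion = lesion_at(unit_grid, block)
        sel = select_damaged_streamlines(t, lesion)
        assert len(sel) > 0
        rev = Tractogram([s[::-1].copy() for s in t.streamlines], unit_grid)
        d1 = np.asarray(distance_volume(t, sel, lesion).data)
        d2 = np.asarray(distance_volume(rev, sel, lesion).data)
        np.testing.assert_allclose(d1, d2, equal_nan=True, atol=1e-12)

    def test_matches_per_point_oracle(self, unit_grid):
        rng = np.random.default_rng(11)
        t = random_tractogram(unit_grid, rng, 25)
        lesion = lesion_at(unit_grid, [(5, 5, 5), (6, 5, 5)])
        sel = select_damaged_streamlines(t, lesion)
        d = np.asarray(distance_volume(t, sel, lesion).data)
        # recompute with loops: per streamline per voxel min of point distances
        acc, cnt = {}, {}
        for i in sel:
            pts = t.streamlines[i]
            hits = np.array(
                [
                    np.asarray(lesion.volume.data)[tuple(unit_grid.world_to_voxel(p))] > 0
                    if unit_grid.in_bounds(unit_grid.world_to_voxel(p))
                    else False
                    for p in pts
                ]
            )
            dist = oracle_polyline_distances(pts, hits)
            per_voxel = {}
            for p, dd in zip(pts, dist):
                v = tuple(unit_grid.world_to_voxel(p))
                if unit_grid.in_bounds(np.array(v)):
                    per_voxel[v] = min(per_voxel.get(v, np.inf), dd)
            for v, dd in per_voxel.items():
                acc[v] = acc.get(v, 0.0) + dd
                cnt[v] = cnt.get(v, 0) + 1
        for v, total in acc.items():
            assert d[v] == pytest.approx(total / cnt[v], abs=1e-9)


def _model_pair(grid, count_data, dist_data):
    return (VolumeImage(grid, count_data), VolumeImage(grid, dist_data))


class TestAveraging:
    def test_single_subject_identity(self, unit_grid):
        c = np.zeros(unit_grid.dims)
        c[1, 1, 1] = 2.0
        d = np.full(unit_grid.dims, np.nan)
        d[1, 1, 1] = 10.0
        m = average_models([_model_pair(unit_grid, c, d)])
        assert m.n_subjects == 1
        np.testing.assert_array_equal(np.asarray(m.count.data), c)
        np.testing.assert_allclose(np.asarray(m.distance.data), d, equal_nan=True)

    def test_idempotent_on_identical(self, unit_grid):
        c = np.zeros(unit_grid.dims)
        c[2, 2, 2] = 3.0
        d = np.full(unit_grid.dims, np.nan)
        d[2, 2, 2] = 7.0
        pair = _model_pair(unit_grid, c, d)
        m = average_models([pair] * 4)
        np.testing.assert_array_equal(np.asarray(m.count.data), c)
        np.testing.assert_allclose(np.asarray(m.distance.data), d, equal_nan=True)

    def test_count_weighted_distance(self, unit_grid):
        c1, c2 = np.zeros(unit_grid.dims), np.zeros(unit_grid.dims)
        d1, d2 = np.full(unit_grid.dims, np.nan), np.full(unit_grid.dims, np.nan)
        c1[0, 0, 0], d1[0, 0, 0] = 2.0, 10.0
        c2[0, 0, 0], d2[0, 0, 0] = 4.0, 20.0
        m = average_models([_model_pair(unit_grid, c1, d1), _model_pair(unit_grid, c2, d2)])
        assert np.asarray(m.count.data)[0, 0, 0] == pytest.approx(3.0)
        assert np.asarray(m.distance.data)[0, 0, 0] == pytest.approx((2 * 10 + 4 * 20) / 6)

    def test_subject_with_zero_count_still_dilutes_mean(self, unit_grid):
        c1, c2 = np.zeros(unit_grid.dims), np.zeros(unit_grid.dims)
        d1, d2 = np.full(unit_grid.dims, np.nan), np.full(unit_grid.dims, np.nan)
        c1[0, 0, 0], d1[0, 0, 0] = 6.0, 12.0
        m = average_models([_model_pair(unit_grid, c1, d1), _model_pair(unit_grid, c2, d2)])
        assert np.asarray(m.count.data)[0, 0, 0] == pytest.approx(3.0)
        # distance ignores the zero-count subject
        assert np.asarray(m.distance.data)[0, 0, 0] == pytest.approx(12.0)

    def test_linearity(self, unit_grid):
        rng = np.random.default_rng(0)
        ca, cb = rng.integers(0, 5, unit_grid.dims).astype(float), rng.integers(
            0, 5, unit_grid.dims
        ).astype(float)
        da = np.where(ca > 0, rng.uniform(1, 30, unit_grid.dims), np.nan)
        db = np.where(cb > 0, rng.uniform(1, 30, unit_grid.dims), np.nan)
        A, B = _model_pair(unit_grid, ca, da), _model_pair(unit_grid, cb, db)
        m1 = average_models([A, A, B, B])
        m2 = average_models([A, B])
        np.testing.assert_allclose(
            np.asarray(m1.count.data), np.asarray(m2.count.data), atol=1e-12
        )
        np.testing.assert_allclose(
            np.asarray(m1.distance.data), np.asarray(m2.distance.data),
            equal_nan=True, atol=1e-12,
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_models([])


class TestStandardizeHemisphere:
    def _model(self, grid):
        c = np.zeros(grid.dims)
        c[2, 3, 4] = 5.0
        d = np.full(grid.dims, np.nan)
        d[2, 3, 4] = 8.0
        return DamageModel(VolumeImage(grid, c), VolumeImage(grid, d), 1)

    def test_left_deficit_identity(self, unit_grid):
        m = self._model(unit_grid)
        out = standardize_hemisphere(m, "left")
        np.testing.assert_array_equal(np.asarray(out.count.data), np.asarray(m.count.data))

    def test_right_deficit_mirrors_index(self, unit_grid):
        out = standardize_hemisphere(self._model(unit_grid), "right")
        assert np.asarray(out.count.data)[7, 3, 4] == 5.0
        assert np.asarray(out.count.data)[2, 3, 4] == 0.0
        assert np.asarray(out.distance.data)[7, 3, 4] == 8.0

    def test_involution_and_multiset(self, unit_grid):
        rng = np.random.default_rng(2)
        c = rng.integers(0, 4, unit_grid.dims).astype(float)
        d = np.where(c > 0, rng.uniform(0, 20, unit_grid.dims), np.nan)
        m = DamageModel(VolumeImage(unit_grid, c), VolumeImage(unit_grid, d), 1)
        once = standardize_hemisphere(m, "right")
        twice = standardize_hemisphere(once, "right")
        np.testing.assert_array_equal(np.asarray(twice.count.data), c)
        assert sorted(np.asarray(once.count.data).ravel()) == sorted(c.ravel())
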