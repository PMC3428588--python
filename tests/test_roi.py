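"""ROI construction, morphology, and precision conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brainbehavior import (
    GridSpec,
    ROIMask,
    clip_halfspace,
    dilate,
    load_mask,
    make_grid,
    mask_volume,
    resample_mask,
    roi_from_labels,
    roi_from_statmap,
    roi_sphere,
    save_mask,
)

from _oracles import dilate_by_hand


@pytest.fixture()
def small_grid():
    return GridSpec(2.0, (-10.0, -10.0, -10.0), (11, 11, 11))


class TestStatmapThreshold:
    def test_constant_below_threshold_gives_empty(self, small_grid):
        data = np.zeros(small_grid.shape)
        assert roi_from_statmap(data, small_grid, 2.5).n_voxels == 0

    def test_threshold_is_closed(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[:7, 0, 0] = 3.0  # exactly at threshold: kept
        assert roi_from_statmap(data, small_grid, 3.0).n_voxels == 7

    def test_minus_infinity_threshold_keeps_everything(self, small_grid):
        data = np.random.default_rng(0).normal(size=small_grid.shape)
        mask = roi_from_statmap(data, small_grid, -np.inf)
        assert mask.n_voxels == small_grid.n_voxels

    def test_non_finite_voxels_are_sub_threshold(self, small_grid):
        data = np.full(small_grid.shape, 5.0)
        data[0, 0, 0] = np.nan
        mask = roi_from_statmap(data, small_grid, 2.5)
        assert mask.n_voxels == small_grid.n_voxels - 1


class TestLabelSelection:
    def test_label_selection(self, small_grid):
        atlas = np.zeros(small_grid.shape, dtype=np.int64)
        atlas[:3] = 1
        atlas[3:5] = 2
        assert roi_from_labels(atlas, small_grid, set()).n_voxels == 0
        m2 = roi_from_labels(atlas, small_grid, {2})
        assert m2.n_voxels == int((atlas == 2).sum())
        union = roi_from_labels(atlas, small_grid, {1, 2})
        assert union.n_voxels == int((atlas >= 1).sum())


class TestSphere:
    def test_tiny_radius_is_single_voxel(self, small_grid):
        center = small_grid.voxel_to_coord([5, 5, 5])
        assert roi_sphere(center, 0.5, small_grid).n_voxels == 1

    @pytest.mark.parametrize("spacing, tol", [(1.0, 0.03), (2.0, 0.06)])
    def test_sphere_volume_close_to_analytic(self, spacing, tol):
        grid = make_grid(spacing)
        mask = roi_sphere((-1.0, 4.0, 48.0), 12.0, grid)
        analytic = 4.0 / 3.0 * np.pi * 12.0 ** 3
        assert abs(mask.volume_mm3 - analytic) <= tol * analytic


class TestDilate:
    def test_zero_iterations_is_identity(self, small_grid):
        mask = roi_sphere((0, 0, 0), 4, small_grid)
        assert np.array_equal(dilate(mask, 0).data, mask.data)

    @pytest.mark.parametrize("iterations, expected", [(1, 27), (2, 125)])
    def test_single_voxel_growth(self, small_grid, iterations, expected):
        data = np.zeros(small_grid.shape, dtype=bool)
        data[5, 5, 5] = True
        assert dilate(ROIMask(small_grid, data), iterations).n_voxels == expected

    def test_matches_brute_force_oracle(self, small_grid, rng):
        data = rng.random(small_grid.shape) > 0.97
        mask = ROIMask(small_grid, data)
        for it in (1, 2):
            expected = dilate_by_hand(map(tuple, np.argwhere(data)), small_grid.shape, it)
            got = set(map(tuple, np.argwhere(dilate(mask, it).data)))
            assert got == expected

    @given(st.integers(0, 2), st.integers(0, 123456))
    def test_monotone(self, iterations, seed):
        grid = GridSpec(2.0, (0, 0, 0), (9, 9, 9))
        data = np.random.default_rng(seed).random(grid.shape) > 0.9
        mask = ROIMask(grid, data)
        out = dilate(mask, iterations)
        assert np.all(out.data[mask.data])  # mask subset of dilation

    def test_commutes_with_translation(self, small_grid, rng):
        data = np.zeros(small_grid.shape, dtype=bool)
        data[3:6, 4:6, 3:5] = rng.random((3, 2, 2)) > 0.4
        mask = ROIMask(small_grid, data)
        shifted = ROIMask(small_grid, np.roll(data, 2, axis=0))
        a = np.roll(dilate(mask, 1).data, 2, axis=0)
        b = dilate(shifted, 1).data
        assert np.array_equal(a, b)


class TestClip:
    def test_posterior_clip(self):
        grid = make_grid(2)
        mask = roi_sphere((0, -27, 0), 10, grid)
        post = clip_halfspace(mask, "y", -27.0, keep="negative")
        ant = clip_halfspace(mask, "y", -27.0, keep="positive")
        ys = grid.axis_coords(1)
        set_y = ys[np.argwhere(post.data)[:, 1]]
        assert set_y.max() <= -27.0
        # the cutoff plane is kept on both sides; elsewhere they partition
        assert post.n_voxels + ant.n_voxels >= mask.n_voxels


class TestResample:
    def test_up_then_down_is_identity(self):
        grid = make_grid(2)
        mask = roi_sphere((10, 10, 10), 9, grid)
        up = resample_mask(mask, 1.0)
        assert up.grid == grid.child()
        assert up.volume_mm3 == mask.volume_mm3  # exact volume preservation
        down = resample_mask(up, 2.0)
        assert down.grid == grid
        assert np.array_equal(down.data, mask.data)

    def test_single_fine_voxel_vanishes_under_majority(self):
        grid = make_grid(2).child()
        data = np.zeros(grid.shape, dtype=bool)
        data[10, 10, 10] = True
        down = resample_mask(ROIMask(grid, data), 2.0)
        assert down.n_voxels == 0  # 1 of 8 children is below the majority
        assert resample_mask(ROIMask(grid, data), 2.0, rule="any").n_voxels == 1

    def test_full_grid_stays_full(self):
        grid = make_grid(2)
        full = ROIMask(grid, np.ones(grid.shape, dtype=bool))
        assert resample_mask(full, 1.0).n_voxels == 8 * grid.n_voxels
        assert resample_mask(resample_mask(full, 1.0), 2.0).n_voxels == grid.n_voxels

    def test_solid_blob_survives_round_trip(self):
        from scipy import ndimage

        grid = make_grid(2).child()
        blob = roi_sphere((0, 0, 0), 10, grid)
        back = resample_mask(resample_mask(blob, 2.0), 1.0)
        # a solid blob loses at most its one-voxel boundary shell
        interior = ndimage.binary_erosion(blob.data, structure=np.ones((3, 3, 3)))
        assert back.n_voxels >= int(interior.sum())
        assert np.all(back.data[interior])

    def test_unsupported_spacing_rejected(self):
        grid = GridSpec(3.0, (0, 0, 0), (4, 4, 4))
        mask = ROIMask(grid, np.ones(grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            resample_mask(mask, 1.0)


class TestVolumeAndIO:
    def test_mask_volume(self, small_grid):
        data = np.zeros(small_grid.shape, dtype=bool)
        assert mask_volume(ROIMask(small_grid, data)) == 0.0
        data.ravel()[:1000] = True
        assert mask_volume(ROIMask(small_grid, data)) == 8000.0
        one = GridSpec(1.0, (0, 0, 0), (3, 3, 3))
        d = np.zeros(one.shape, dtype=bool)
        d[0, 0, 0] = True
        assert mask_volume(ROIMask(one, d)) == 1.0

    def test_nifti_round_trip(self, tmp_path):
        grid = make_grid(2)
        mask = roi_sphere((4, -10, 22), 9, grid)
        path = tmp_path / "mask.nii.gz"
        save_mask(mask, path)
        back = load_mask(path)
        assert back.grid == grid
        assert np.array_equal(back.data, mask.data)
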