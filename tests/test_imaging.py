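"""Segmentation post-processing against exhaustive voxel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arguide.imaging import (LabelMask, VolumeImage, extract_surface, fill_holes,
                             keep_largest_components, threshold_mask)


def make_volume(arr, spacing=(1, 1, 1)):
    return VolumeImage(np.asarray(arr), spacing)


class TestThreshold:
    def test_all_background_empty(self):
        vol = make_volume(np.zeros((8, 8, 8)))
        assert threshold_mask(vol, 300, 3000).count() == 0

    def test_block_voxel_count_oracle(self):
        """Exhaustive scan oracle: exactly the 10^3 block voxels survive."""
        arr = np.full((20, 20, 20), -1000.0)
        arr[5:15, 5:15, 5:15] = 1000.0
        mask = threshold_mask(make_volume(arr), 300)
        oracle = sum(1 for v in arr.ravel() if v >= 300)
        assert mask.count() == oracle == 1000

    def test_cortical_shell(self):
        """Thresholding a shell-like bone keeps only shell voxels."""
        ii, jj, kk = np.mgrid[:24, :24, :24]
        r = np.sqrt((ii - 12.0) ** 2 + (jj - 12.0) ** 2)
        arr = np.where((r > 6) & (r < 9), 1200.0, np.where(r <= 6, 50.0, -1000.0))
        mask = threshold_mask(make_volume(arr), 300)
        assert mask.count() > 0
        assert np.array_equal(mask.voxels.astype(bool), (arr >= 300))

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            threshold_mask(make_volume(np.zeros((4, 4, 4))), 100, 50)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vol = make_volume(rng.normal(0, 500, (6, 6, 6)))
        m1 = threshold_mask(vol, 100, 800)
        m2 = threshold_mask(VolumeImage(m1.voxels, m1.spacing, m1.origin), 1, 1)
        assert np.array_equal(m1.voxels, m2.voxels)


def _flood_fill_sizes(vox):
    """Independent 26-connectivity component oracle (BFS)."""
    vox = vox.astype(bool)
    seen = np.zeros_like(vox)
    sizes = []
    nbrs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for idx in zip(*np.nonzero(vox)):
        if seen[idx]:
            continue
        stack, size = [idx], 0
        seen[idx] = True
        while stack:
            i, j, k = stack.pop()
            size += 1
            for a, b, c in nbrs:
                n = (i + a, j + b, k + c)
                if all(0 <= n[d] < vox.shape[d] for d in range(3)) and vox[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestIslands:
    def test_single_component_identity(self):
        arr = np.zeros((10, 10, 10), np.uint8)
        arr[2:8, 2:8, 2:8] = 1
        m = LabelMask(arr)
        assert np.array_equal(keep_largest_components(m, 1).voxels, arr)

    def test_two_blocks_flood_fill_oracle(self):
        arr = np.zeros((24, 24, 24), np.uint8)
        arr[1:11, 1:11, 1:11] = 1       # 1000 voxels
        arr[18:21, 18:21, 18:21] = 1    # 27 voxels
        m = keep_largest_components(LabelMask(arr), 1)
        assert _flood_fill_sizes(arr) == [1000, 27]
        assert m.count() == 1000
        assert m.voxels[19, 19, 19] == 0

    def test_bed_slab_removed(self):
        """A disjoint flat slab (the 'clinical bed') is discarded."""
        arr = np.zeros((30, 30, 20), np.uint8)
        arr[5:25, 5:25, 8:14] = 1          # bone block
        arr[:, :, 0:2] = 1                 # bed slab, disconnected
        m = keep_largest_components(LabelMask(arr), 1)
        assert m.voxels[:, :, 0:2].sum() == 0
        assert m.voxels[5:25, 5:25, 8:14].all()

    def test_never_increases_and_saturates(self):
        arr = np.zeros((12, 12, 12), np.uint8)
        arr[0:3, 0:3, 0:3] = 1
        arr[6:9, 6:9, 6:9] = 1
        m = LabelMask(arr)
        assert keep_largest_components(m, 2).count() == m.count()
        assert keep_largest_components(m, 5).count() == m.count()
        assert keep_largest_components(m, 1).count() <= m.count()

    def test_empty_mask_warns(self, caplog):
        m = LabelMask(np.zeros((4, 4, 4), np.uint8))
        out = keep_largest_components(m, 1)
        assert out.count() == 0


class TestFillHoles:
    def test_solid_block_unchanged(self):
        arr = np.zeros((12, 12, 12), np.uint8)
        arr[2:10, 2:10, 2:10] = 1
        out = fill_holes(LabelMask(arr))
        assert np.array_equal(out.voxels, arr)

    def test_internal_cavity_filled_oracle(self):
        """Brute-force dilation-then-erosion oracle on a cavity block."""
        from scipy import ndimage

        arr = np.zeros((16, 16, 10), np.uint8)
        arr[2:14, 2:14, 2:8] = 1
        arr[7:10, 7:10, 4] = 0  # 3x3x1 cavity
        kernel = np.ones((7, 7, 3), bool)
        pad = np.pad(arr.astype(bool), 8)
        oracle = ndimage.binary_erosion(ndimage.binary_dilation(pad, kernel), kernel)[8:-8, 8:-8, 8:-8]
        out = fill_holes(LabelMask(arr))
        assert out.voxels[8, 8, 4] == 1
        assert np.array_equal(out.voxels.astype(bool), oracle | arr.astype(bool))

    def test_no_interior_cavities_remain(self):
        """Speckled holes smaller than the kernel all close."""
        from scipy import ndimage

        rng = np.random.default_rng(3)
        arr = np.zeros((20, 20, 12), np.uint8)
        arr[2:18, 2:18, 2:10] = 1
        holes = rng.integers(4, 16, (20, 3))
        for i, j, k in holes:
            if 3 <= k <= 8:
                arr[i, j, k] = 0
        out = fill_holes(LabelMask(arr))
        filled = ndimage.binary_fill_holes(out.voxels)
        assert np.array_equal(filled, out.voxels.astype(bool))

    def test_superset_and_idempotent(self):
        rng = np.random.default_rng(9)
        arr = (rng.random((10, 10, 10)) > 0.6).astype(np.uint8)
        m = LabelMask(arr)
        once = fill_holes(m)
        twice = fill_holes(once)
        assert (once.voxels >= arr).all()
        assert np.array_equal(once.voxels, twice.voxels)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            fill_holes(LabelMask(np.ones((4, 4, 4), np.uint8)), kernel=(6, 7, 3))


class TestExtractSurface:
    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            extract_surface(LabelMask(np.zeros((4, 4, 4), np.uint8)))

    def test_cube_volume(self):
        arr = np.zeros((14, 14, 14), np.uint8)
        arr[2:12, 2:12, 2:12] = 1
        m = extract_surface(LabelMask(arr, spacing=(1, 1, 1)))
        assert m.is_watertight()
        assert abs(m.volume() - 1000.0) / 1000.0 < 0.15

    def test_sphere_volume_and_physical_coords(self):
        ii, jj, kk = np.mgrid[:26, :26, :26]
        r = np.sqrt((ii - 12.5) ** 2 + (jj - 12.5) ** 2 + (kk - 12.5) ** 2)
        arr = (r <= 10).astype(np.uint8)
        mask = LabelMask(arr, spacing=(1, 1, 1), origin=(-10, 5, 0))
        m = extract_surface(mask)
        exact = 4.0 / 3.0 * np.pi * 1000.0
        assert abs(m.volume() - exact) / exact < 0.10
        centre = m.vertices.mean(axis=0)
        assert np.allclose(centre, np.array([12.5, 12.5, 12.5]) + [-10, 5, 0], atol=0.5)

    def test_anisotropic_spacing_scales_volume(self):
        arr = np.zeros((12, 12, 12), np.uint8)
        arr[2:10, 2:10, 2:10] = 1
        m1 = extract_surface(LabelMask(arr, spacing=(1, 1, 1)))
        m2 = extract_surface(LabelMask(arr, spacing=(1, 1, 2.5)))
        assert abs(m2.volume() / m1.volume() - 2.5) < 0.05
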