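"""Pre-processing, FCM segmentation, mask cleanup and erosion."""

import numpy as np
import pytest

from pituradiomics import (BoundingROI, ImageVolume, LesionMask, dice,
                           erode_shell, fcm_segment, normalize_roi,
                           postprocess_mask, resample_isotropic, transfer_mask)
from pituradiomics.segmentation import fuzzy_cmeans_1d

from conftest import make_mask, make_volume, sphere_mask


class TestResampleIsotropic:
    def test_isotropic_input_is_identity(self):
        vol = make_volume(np.random.default_rng(0).normal(size=(10, 12, 8)))
        out = resample_isotropic(vol, 1.0)
        assert out.spacing == (1.0, 1.0, 1.0)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_constant_volume_stays_constant(self):
        vol = make_volume(np.full((8, 8, 4), 7.5), spacing=(1, 1, 3))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.data, 7.5)

    def test_linear_ramp_preserved(self):
        # trilinear interpolation is exact on a linear field
        z = np.arange(6)[None, None, :] * np.ones((8, 8, 1))
        vol = make_volume(z * 3.0, spacing=(1, 1, 3))
        out = resample_isotropic(vol, 1.0)
        expected = np.arange(out.shape[2]) * 1.0  # 3 mm/step over 3x finer grid
        err = np.abs(out.data - expected[None, None, :]).max()
        assert err < 1e-6 * (z.max() * 3)

    def test_world_extent_preserved(self):
        vol = make_volume(np.zeros((10, 10, 10)), spacing=(0.8, 1.0, 2.5))
        out = resample_isotropic(vol, 0.8)
        old_extent = np.array(vol.shape) * np.array(vol.spacing)
        new_extent = np.array(out.shape) * 0.8
        assert np.all(np.abs(old_extent - new_extent) <= np.array(vol.spacing) + 0.8)


class TestNormalizeRoi:
    def test_three_voxel_hand_computation(self):
        vol = make_volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        mask = make_mask(np.ones((3, 1, 1)))
        out = normalize_roi(vol, mask)
        expected = np.array([-1.2247448714, 0.0, 1.2247448714])  # population SD
        np.testing.assert_allclose(out.data.ravel(), expected, atol=1e-9)

    def test_idempotent_on_standardized_roi(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 6, 6))
        mask = make_mask(rng.uniform(size=(6, 6, 6)) < 0.5)
        vol = normalize_roi(make_volume(data), mask)
        again = normalize_roi(vol, mask)
        np.testing.assert_allclose(again.data, vol.data, atol=1e-10)

    def test_postcondition_mean0_sd1(self):
        rng = np.random.default_rng(2)
        vol = make_volume(rng.normal(3, 5, size=(8, 8, 8)))
        mask = make_mask(rng.uniform(size=(8, 8, 8)) < 0.4)
        out = normalize_roi(vol, mask)
        vals = out.data[mask.data]
        assert abs(vals.mean()) < 1e-10 and abs(vals.std() - 1) < 1e-10

    def test_zero_variance_rejected(self):
        vol = make_volume(np.ones((4, 4, 4)))
        mask = make_mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="variance"):
            normalize_roi(vol, mask)


class TestFuzzyCMeans:
    def test_well_separated_matches_threshold_oracle(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.0, 1.0, size=(30, 30))
        hi = rng.normal(10.0, 1.0, size=(30, 10))  # Δμ = 10σ
        img = np.concatenate([lo, hi], axis=1)[..., None]
        vol = make_volume(img)
        roi = BoundingROI(rect=(0, 30, 0, 40), slice_range=(0, 1))
        seg = fcm_segment(vol, roi, seed=0)
        # brute-force optimal threshold over all candidate cuts
        vals = np.sort(img.ravel())
        truth = img >= 5.0
        best = max(((img >= t) == truth).mean() for t in vals)
        got = (seg.data == truth).mean()
        assert got >= best - 1e-12
        assert dice(seg.data, truth) == 1.0

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(3, 1, 200)])
        res = fuzzy_cmeans_1d(x, n_clusters=2, seed=1)
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * hist[0])

    def test_constant_slice_rejected(self):
        vol = make_volume(np.ones((5, 5, 1)))
        roi = BoundingROI(rect=(0, 5, 0, 5), slice_range=(0, 1))
        with pytest.raises(ValueError, match="distinct"):
            fcm_segment(vol, roi)

    def test_determinism(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        a = fuzzy_cmeans_1d(x, seed=5)
        b = fuzzy_cmeans_1d(x, seed=5)
        np.testing.assert_array_equal(a.membership, b.membership)


class TestPostprocessMask:
    def test_distant_speck_removed(self):
        m = np.zeros((20, 20, 5), dtype=bool)
        m[5:12, 5:12, 1:4] = True
        m[18, 18, 4] = True
        out = postprocess_mask(make_mask(m))
        assert not out.data[18, 18, 4]
        assert out.data[8, 8, 2]

    def test_hollow_sphere_filled_to_solid(self):
        solid = sphere_mask(8.0)
        shape = solid.shape
        c = [(n - 1) / 2 for n in shape]
        gx, gy, gz = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
        r2 = (gx - c[0])**2 + (gy - c[1])**2 + (gz - c[2])**2
        hollow = (r2 <= 8.0**2) & (r2 > 5.0**2)
        out = postprocess_mask(make_mask(hollow))
        assert out.n_voxels == pytest.approx(solid.n_voxels, rel=0.02)

    def test_idempotent_on_clean_mask(self):
        mask = sphere_mask(6.0)
        once = postprocess_mask(mask)
        twice = postprocess_mask(once)
        assert np.array_equal(once.data, twice.data)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            postprocess_mask(make_mask(np.zeros((4, 4, 4))))


class TestTransferMask:
    def test_identity_same_grid_exact(self):
        mask = sphere_mask(6.0)
        target = make_volume(np.zeros(mask.shape))
        out = transfer_mask(mask, np.eye(4), target)
        assert np.array_equal(out.data, mask.data)

    def test_integer_translation_exact(self):
        mask = sphere_mask(5.0)
        target = make_volume(np.zeros(mask.shape))
        aff = np.eye(4)
        aff[:3, 3] = [2, -1, 1]  # target voxel -> source voxel shift
        out = transfer_mask(mask, aff, target)
        expected = np.zeros_like(mask.data)
        expected[:-2, 1:, :-1] = mask.data[2:, :-1, 1:]
        assert np.array_equal(out.data, expected)

    def test_rigid_rotation_matches_analytic_sphere(self):
        # rotating a centered sphere maps it onto itself
        mask = sphere_mask(10.0)
        target = make_volume(np.zeros(mask.shape))
        theta = 0.35
        c = np.array([(n - 1) / 2 for n in mask.shape])
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1]])
        aff = np.eye(4)
        aff[:3, :3] = R
        aff[:3, 3] = c - R @ c
        out = transfer_mask(mask, aff, target)
        assert dice(out, mask) > 0.95

    def test_singular_affine_rejected(self):
        mask = sphere_mask(4.0)
        bad = np.zeros((4, 4))
        with pytest.raises(ValueError, match="invertible"):
            transfer_mask(mask, bad, make_volume(np.zeros(mask.shape)))


class TestErodeShell:
    def test_sphere_erosion_matches_analytic(self):
        mask = sphere_mask(20.0)
        out = erode_shell(mask, 0.25)
        analytic = 4.0 / 3.0 * np.pi * 17.5**3
        assert abs(out.volume_mm3 - analytic) / analytic < 0.10
        assert out.variant == "eroded_025"

    def test_depth_zero_is_identity(self):
        mask = sphere_mask(5.0)
        out = erode_shell(mask, 0.0)
        assert np.array_equal(out.data, mask.data)

    def test_small_sphere_emptied_raises(self):
        mask = sphere_mask(4.0)
        with pytest.raises(ValueError, match="original"):
            erode_shell(mask, 0.5)

    def test_nesting_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            base = sphere_mask(rng.uniform(12, 18))
            e25 = erode_shell(base, 0.25)
            e50 = erode_shell(base, 0.5)
            assert np.all(e50.data <= e25.data)
            assert np.all(e25.data <= base.data)

    def test_retained_voxels_respect_depth(self):
        from scipy.ndimage import distance_transform_edt
        mask = sphere_mask(12.0, spacing=(0.8, 0.8, 2.0))
        out = erode_shell(mask, 0.25)
        d = distance_transform_edt(mask.data, sampling=mask.spacing)
        assert np.all(d[out.data] >= 2.5)
        assert out.n_voxels < mask.n_voxels
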