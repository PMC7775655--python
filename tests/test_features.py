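"""Radiomics feature bank: hand examples, brute-force oracles, invariances."""

import numpy as np
import pytest

from pituradiomics import FEATURE_NAMES, LesionMask, extract_all
from pituradiomics.features import (discretize, first_order_features,
                                    gldm_features, gldm_matrix, glcm_features,
                                    glcm_matrix, glrlm_features, glrlm_matrix,
                                    glszm_features, glszm_matrix,
                                    ngtdm_features, ngtdm_matrix,
                                    shape_features)
from pituradiomics.features._directions import DIRECTIONS_13
from pituradiomics.features.ngtdm import COARSENESS_SENTINEL
from pituradiomics import PhantomSpec, generate_phantom

from conftest import levels_to_roi, make_mask, make_volume, sphere_mask
import oracles


class TestDiscretize:
    def test_integer_ramp_maps_to_consecutive_levels(self):
        data = np.arange(32, dtype=float).reshape(32, 1, 1)
        d = discretize(make_volume(data), make_mask(np.ones((32, 1, 1))), n_bins=32)
        np.testing.assert_array_equal(d.levels.ravel(), np.arange(1, 33))

    def test_constant_roi_single_level_with_warning(self):
        vol = make_volume(np.full((4, 4, 1), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            d = discretize(vol, make_mask(np.ones((4, 4, 1))))
        assert set(d.in_mask_levels) == {1}

    def test_level_histogram_conserves_voxel_count(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        mask = make_mask(rng.uniform(size=(6, 6, 6)) < 0.6)
        d = discretize(vol, mask, n_bins=8)
        assert d.in_mask_levels.size == mask.n_voxels
        assert d.in_mask_levels.min() >= 1 and d.in_mask_levels.max() <= 8


class TestFirstOrder:
    def test_three_voxel_hand_values(self):
        vol = make_volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        f = first_order_features(vol, make_mask(np.ones((3, 1, 1))))
        assert f["mean"] == 2.0
        assert f["range"] == 2.0
        assert f["median"] == 2.0

    def test_constant_roi_degenerate_conventions(self):
        vol = make_volume(np.full((3, 3, 1), 4.0))
        f = first_order_features(vol, make_mask(np.ones((3, 3, 1))))
        assert f["variance"] == 0.0 and f["entropy"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0

    def test_moments_match_direct_computation(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(1000)
        vol = make_volume(x.reshape(10, 10, 10))
        f = first_order_features(vol, make_mask(np.ones((10, 10, 10))))
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert f["skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert f["kurtosis"] == pytest.approx(m4 / m2**2 - 3.0, abs=1e-12)
        assert abs(f["skewness"]) < 0.25  # standard-normal sample


class TestShape:
    def test_sphere_surface_to_volume(self):
        mask = sphere_mask(10.0)
        f = shape_features(mask)
        assert f["surface_to_volume_ratio"] == pytest.approx(0.3, rel=0.05)
        assert f["maximum_3d_diameter"] == pytest.approx(20.0, rel=0.08)
        assert f["sphericity"] == pytest.approx(1.0, rel=0.05)

    def test_cube_surface_to_volume(self):
        m = np.zeros((26, 26, 26), dtype=bool)
        m[3:23, 3:23, 3:23] = True  # 20 mm cube at 1 mm spacing
        f = shape_features(LesionMask(m, (1, 1, 1)))
        assert f["surface_to_volume_ratio"] == pytest.approx(6.0 / 20.0, rel=0.05)

    def test_scaling_halves_ratio(self):
        mask1 = sphere_mask(8.0)
        mask2 = LesionMask(mask1.data, (2.0, 2.0, 2.0))  # same grid, 2x spacing
        r1 = shape_features(mask1)["surface_to_volume_ratio"]
        r2 = shape_features(mask2)["surface_to_volume_ratio"]
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-6)

    def test_elongation_flatness_in_unit_interval(self):
        f = shape_features(sphere_mask(6.0))
        assert 0.9 < f["elongation"] <= 1.0 + 1e-9
        assert 0.9 < f["flatness"] <= 1.0 + 1e-9


class TestGlcm:
    def test_two_by_two_hand_example(self):
        # [[1,1],[2,2]] single slice; exhaustive pair enumeration oracle
        lv = np.array([[1, 1], [2, 2]], dtype=np.int32)[..., None]
        d = levels_to_roi(lv, 2)
        for direction in DIRECTIONS_13:
            mine = glcm_matrix(d, direction)
            ref = oracles.bf_glcm(lv, 2, direction)
            np.testing.assert_array_equal(mine, ref)
        f = glcm_features(d)
        assert np.isfinite(f["informational_measure_of_correlation_1"])

    def test_constant_roi_imc1_zero(self):
        lv = np.ones((3, 3, 1), dtype=np.int32)
        f = glcm_features(levels_to_roi(lv, 4))
        assert f["informational_measure_of_correlation_1"] == 0.0

    def test_single_voxel_rejected(self):
        lv = np.zeros((3, 3, 1), dtype=np.int32)
        lv[1, 1, 0] = 1
        with pytest.raises(ValueError, match="pairs"):
            glcm_features(levels_to_roi(lv, 2))

    def test_checkerboard_contrast_is_maximal_along_axes(self):
        # every axis-aligned neighbor pair of a checkerboard differs, so its
        # per-direction contrast is the 2-level maximum (= 1); no image of
        # the same size can exceed it (brute-force matrix oracle)
        def axis_contrast(lv, direction):
            P = oracles.bf_glcm(lv, 2, direction)
            P = P / P.sum()
            i, j = np.indices(P.shape)
            return ((i - j) ** 2 * P).sum()

        rng = np.random.default_rng(5)
        idx = np.indices((4, 4, 1)).sum(axis=0)
        checker = (idx % 2 + 1).astype(np.int32)
        for direction in ((1, 0, 0), (0, 1, 0)):
            c_check = axis_contrast(checker, direction)
            assert c_check == pytest.approx(1.0)
            for _ in range(20):
                rand = rng.integers(1, 3, size=(4, 4, 1)).astype(np.int32)
                if rand.min() == rand.max():
                    continue
                assert axis_contrast(rand, direction) <= c_check + 1e-12

    def test_probability_matrix_sums_to_one(self, tiny_level_fixtures):
        for lv, ng in tiny_level_fixtures:
            d = levels_to_roi(lv, ng)
            for direction in DIRECTIONS_13:
                C = glcm_matrix(d, direction)
                if C.sum() > 0:
                    assert abs((C / C.sum()).sum() - 1.0) < 1e-10


class TestNgtdm:
    def test_uniform_roi_sentinel(self):
        lv = np.ones((4, 4, 2), dtype=np.int32)
        f = ngtdm_features(levels_to_roi(lv, 3))
        assert f["coarseness"] == COARSENESS_SENTINEL

    def test_single_deviant_center_hand_enumeration(self):
        lv = np.ones((3, 3, 1), dtype=np.int32)
        lv[1, 1, 0] = 2
        d = levels_to_roi(lv, 2)
        s, n = ngtdm_matrix(d)
        s_ref, n_ref = oracles.bf_ngtdm(lv, 2)
        np.testing.assert_allclose(s, s_ref, atol=1e-12)
        np.testing.assert_array_equal(n, n_ref)
        # hand check: center deviates by 1 from its 8 neighbors' mean of 1;
        # each edge/corner voxel sees the deviant center in its neighborhood
        assert s[1] == pytest.approx(1.0)
        f = ngtdm_features(d)
        p = n / n.sum()
        assert f["coarseness"] == pytest.approx(1.0 / (p @ s))

    def test_probabilities_sum_to_one(self, tiny_level_fixtures):
        for lv, ng in tiny_level_fixtures:
            _, n = ngtdm_matrix(levels_to_roi(lv, ng))
            if n.sum():
                assert abs((n / n.sum()).sum() - 1.0) < 1e-10


class TestRunZoneDependence:
    def test_single_level_roi_is_one_zone(self):
        lv = np.ones((3, 4, 2), dtype=np.int32)
        P = glszm_matrix(levels_to_roi(lv, 2))
        assert P[0, 23] == 1.0 and P.sum() == 1.0

    def test_alternating_line_runs(self):
        lv = np.array([[1, 2, 1, 2, 1, 2]], dtype=np.int32)[..., None]
        P = glrlm_matrix(levels_to_roi(lv, 2), (0, 1, 0))
        assert P[:, 0].sum() == 6  # six runs of length 1
        assert P[:, 1:].sum() == 0

    def test_matrices_match_bruteforce(self, tiny_level_fixtures):
        for lv, ng in tiny_level_fixtures:
            d = levels_to_roi(lv, ng)
            for direction in DIRECTIONS_13[:4]:
                np.testing.assert_array_equal(glrlm_matrix(d, direction),
                                              oracles.bf_glrlm(lv, ng, direction))
            mine_z = glszm_matrix(d)
            ref_z = oracles.bf_glszm(lv, ng)
            np.testing.assert_array_equal(mine_z[:, :ref_z.shape[1]], ref_z)
            np.testing.assert_array_equal(gldm_matrix(d), oracles.bf_gldm(lv, ng))

    def test_feature_values_finite(self, tiny_level_fixtures):
        for lv, ng in tiny_level_fixtures:
            d = levels_to_roi(lv, ng)
            for fn in (glrlm_features, glszm_features, gldm_features):
                assert all(np.isfinite(v) for v in fn(d).values())


class TestExtractAll:
    def test_schema_214_finite(self, small_phantom):
        t1, t2, truth = small_phantom
        feats = extract_all(t1, t2, truth)
        assert list(feats) == FEATURE_NAMES
        assert len(feats) == 214
        assert all(np.isfinite(v) for v in feats.values())

    def test_determinism(self, small_phantom):
        t1, t2, truth = small_phantom
        a = extract_all(t1, t2, truth)
        b = extract_all(t1, t2, truth)
        assert a == b

    def test_intensity_rescale_invariance_of_texture(self, small_phantom):
        # affine intensity rescaling is absorbed by equal-width binning
        t1, t2, truth = small_phantom
        base = extract_all(t1, t2, truth)
        rescaled = extract_all(t1.with_data(3.0 * t1.data + 7.0), t2, truth)
        for name in FEATURE_NAMES:
            fam = name.split("_")[1]
            if name.startswith("t1ce") and fam in ("glcm", "glrlm", "glszm",
                                                   "ngtdm", "gldm"):
                assert rescaled[name] == pytest.approx(base[name], rel=1e-9), name

    def test_inplane_rotation_stability_of_glcm(self):
        spec = PhantomSpec(grid_shape=(36, 36, 36), voxel_spacing_mm=(1, 1, 1),
                           tumor_radii_mm=(10, 10, 10), rng_seed=8)
        t1, t2, truth = generate_phantom(spec)
        base = extract_all(t1, t2, truth)
        rot = extract_all(
            t1.with_data(np.rot90(t1.data, axes=(0, 1))),
            t2.with_data(np.rot90(t2.data, axes=(0, 1))),
            LesionMask(np.rot90(truth.data, axes=(0, 1)), truth.spacing))
        for name in FEATURE_NAMES:
            if "_glcm_" in name:
                assert rot[name] == pytest.approx(base[name], rel=0.01), name

    def test_grid_mismatch_rejected(self, small_phantom):
        t1, t2, truth = small_phantom
        bad = make_volume(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="grid"):
            extract_all(bad, t2, truth)
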