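import numpy as np
import pytest
from _oracles import glcm_oracle, glcm_stats_oracle

from momcrad import (
    EmptyRegionError,
    GLCMSpec,
    RegionMask,
    VolumetricImage,
    extract_all,
    geometry_features,
    glcm_features,
    glcm_matrix,
    glcm_statistics,
    intensity_features,
)
from momcrad.features import DISTANCES, GRAY_LEVELS


def image(vals, modality="CT", units="HU"):
    return VolumetricImage(np.asarray(vals, dtype=float), (1, 1, 1), modality, units)


def full_mask(shape):
    return RegionMask(np.ones(shape, dtype=bool), (1, 1, 1))


class TestGeometry:
    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        fv = geometry_features(RegionMask(m, (1, 1, 1)))
        assert len(fv) == 8
        assert fv.as_dict()["geom_volume_mm3"] == pytest.approx(1.0)

    def test_digital_ball_sphericity_near_one(self):
        r = 10.0
        n = 26
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij")
        ball = zz**2 + yy**2 + xx**2 <= r**2
        fv = geometry_features(RegionMask(ball, (1, 1, 1))).as_dict()
        assert 0.95 <= fv["geom_sphericity"] <= 1.02
        # analytic sphere: V = 4/3 pi r^3, A = 4 pi r^2, diameter 2r
        assert fv["geom_volume_mm3"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.03)
        assert fv["geom_surface_area_mm2"] == pytest.approx(4 * np.pi * r**2, rel=0.05)
        assert fv["geom_max_diameter_mm"] == pytest.approx(2 * r, rel=0.1)
        assert 0.9 <= fv["geom_elongation"] <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRegionError):
            geometry_features(RegionMask(np.zeros((2, 2, 2), dtype=bool), (1, 1, 1)))


class TestIntensity:
    def test_basic_statistics(self):
        vals = np.zeros((1, 1, 3))
        vals[0, 0] = [1.0, 2.0, 3.0]
        fv = intensity_features(image(vals), full_mask((1, 1, 3))).as_dict()
        assert len(fv) == 9
        assert fv["int_mean"] == pytest.approx(2.0)
        assert fv["int_median"] == pytest.approx(2.0)
        assert fv["int_min"] == 1.0 and fv["int_max"] == 3.0
        assert fv["int_energy"] == pytest.approx(14.0)

    def test_constant_region_conventions(self):
        fv = intensity_features(image(np.full((2, 2, 2), 5.0)), full_mask((2, 2, 2))).as_dict()
        assert fv["int_std"] == 0.0
        assert fv["int_entropy"] == 0.0
        assert fv["int_skewness"] == 0.0
        assert fv["int_kurtosis"] == 0.0


class TestGLCMMatrix:
    def test_two_voxel_region(self):
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [0.0, 1.0]
        P = glcm_matrix(image(vals), full_mask((1, 1, 2)), GLCMSpec(2, 1))
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(P, expected)

    def test_constant_region_single_bin(self):
        P = glcm_matrix(image(np.full((2, 2, 2), 3.0)), full_mask((2, 2, 2)), GLCMSpec(8, 1))
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_normalized_and_symmetric(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(6, 6, 6))
        mask = RegionMask(rng.random((6, 6, 6)) > 0.3, (1, 1, 1))
        P = glcm_matrix(image(vals), mask, GLCMSpec(16, 2))
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 40, size=(5, 5, 5)).astype(float)
        mask = rng.random((5, 5, 5)) > 0.25
        mask[2, 2, 2] = True
        for L, d in [(4, 1), (8, 2), (8, 3)]:
            P = glcm_matrix(
                image(vals), RegionMask(mask, (1, 1, 1)), GLCMSpec(L, d)
            )
            np.testing.assert_allclose(P, glcm_oracle(vals, mask, L, d), atol=1e-12)


class TestGLCMFeatures:
    def test_constant_region_contrast_zero_energy_one(self):
        fv = glcm_features(image(np.full((4, 4, 4), 2.0)), full_mask((4, 4, 4)))
        d = fv.as_dict()
        for L in GRAY_LEVELS:
            for dist in DISTANCES:
                assert d[f"glcm_contrast_g{L}_d{dist}"] == 0.0
                assert d[f"glcm_energy_g{L}_d{dist}"] == 1.0

    def test_statistics_match_oracle_on_random_volume(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), dtype=bool)
        fv = glcm_features(image(vals), full_mask((8, 8, 8))).as_dict()
        for L, d in [(8, 1), (16, 4)]:
            P = glcm_oracle(vals, mask, L, d)
            expected = glcm_stats_oracle(P)
            for stat, val in expected.items():
                assert fv[f"glcm_{stat}_g{L}_d{d}"] == pytest.approx(val, abs=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(6, 6, 6))
        mask = full_mask((6, 6, 6))
        a = glcm_features(image(vals), mask).values
        b = glcm_features(image(vals + 137.0), mask).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_rotation_invariance_90_degrees(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(6, 6, 6))
        m = rng.random((6, 6, 6)) > 0.3
        m[3, 3, 3] = True
        a = glcm_features(image(vals), RegionMask(m, (1, 1, 1))).values
        vr = np.rot90(vals, k=1, axes=(0, 1)).copy()
        mr = np.rot90(m, k=1, axes=(0, 1)).copy()
        b = glcm_features(image(vr), RegionMask(mr, (1, 1, 1))).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestExtractAll:
    def test_count_and_partition(self, phantom):
        ct, pet, mask = phantom
        fv = extract_all(pet, mask)
        assert len(fv) == 257
        assert sum(n.startswith("geom_") for n in fv.names) == 8
        assert sum(n.startswith("int_") for n in fv.names) == 9
        assert sum(n.startswith("glcm_") for n in fv.names) == 240
        assert len(set(fv.names)) == 257

    def test_deterministic_order_and_values(self, phantom):
        ct, pet, mask = phantom
        a = extract_all(ct, mask)
        b = extract_all(ct, mask)
        assert a.names == b.names
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_values_finite_on_noiseless_phantom(self, noiseless_phantom):
        ct, pet, mask = noiseless_phantom
        fv = extract_all(pet, mask)
        assert np.all(np.isfinite(fv.values))


def test_degenerate_statistics_convention():
    # zero-variance GLCM: correlation defined as 0, never NaN
    P = np.zeros((4, 4))
    P[0, 0] = 1.0
    stats = glcm_statistics(P)
    assert stats["correlation"] == 0.0
    assert stats["energy"] == 1.0
    assert np.all(np.isfinite(list(stats.values())))
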