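import numpy as np
import pytest

from momcrad import (
    AcquisitionInfo,
    EmptyRegionError,
    InvalidArgumentError,
    RegionMask,
    VolumetricImage,
    compute_suv,
    load_image,
    load_mask,
    resample_isotropic,
    save_image,
    save_mask,
    soft_tissue_mask,
    suv_threshold_region,
)


def ct(values, spacing=(1, 1, 1)):
    return VolumetricImage(np.asarray(values, dtype=float), spacing, "CT", "HU")


class TestResample:
    def test_output_shape_follows_spacing_arithmetic(self):
        img = ct(np.zeros((10, 10, 10)), spacing=(2, 2, 3))
        out = resample_isotropic(img, 1.0)
        assert out.shape == (20, 20, 30)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_identity_when_spacing_matches_target(self):
        vals = np.random.default_rng(0).normal(size=(6, 7, 8))
        out = resample_isotropic(ct(vals), 1.0)
        np.testing.assert_allclose(out.values, vals)

    def test_trilinear_reproduces_linear_fields(self):
        # values a*x + b*y + c*z; the resampled grid must carry the same
        # linear function at the new voxel positions (interior: edge voxels
        # beyond the source extent clamp to constant extrapolation)
        a, b, c = 0.7, -1.3, 2.1
        z, y, x = np.meshgrid(
            np.arange(10) * 3.0, np.arange(10) * 2.0, np.arange(10) * 2.0, indexing="ij"
        )
        img = ct(a * x + b * y + c * z, spacing=(3, 2, 2))
        out = resample_isotropic(img, 1.0)
        zn, yn, xn = np.meshgrid(
            np.arange(out.shape[0]) * 1.0,
            np.arange(out.shape[1]) * 1.0,
            np.arange(out.shape[2]) * 1.0,
            indexing="ij",
        )
        interior = (zn <= 27) & (yn <= 18) & (xn <= 18)
        np.testing.assert_allclose(
            out.values[interior], (a * xn + b * yn + c * zn)[interior], atol=1e-9
        )

    def test_mask_resampling_stays_binary(self):
        rng = np.random.default_rng(3)
        mask = RegionMask(rng.random((9, 9, 9)) > 0.5, (1.7, 1.3, 2.2))
        out = resample_isotropic(mask, 1.0)
        assert set(np.unique(out.values.astype(int))) <= {0, 1}

    def test_nonpositive_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_isotropic(ct(np.zeros((4, 4, 4))), 0.0)

    def test_bbox_commutes_with_resampling_within_one_voxel(self):
        vals = np.zeros((12, 12, 12), dtype=bool)
        vals[3:9, 2:10, 4:8] = True
        mask = RegionMask(vals, (2, 2, 2))
        res_then_crop = resample_isotropic(mask, 1.0)
        idx = np.argwhere(res_then_crop.values)
        ext_a = idx.max(axis=0) - idx.min(axis=0) + 1
        crop = RegionMask(vals[3:9, 2:10, 4:8], (2, 2, 2))
        ext_b = np.array(resample_isotropic(crop, 1.0).shape)
        assert np.all(np.abs(ext_a - ext_b) <= 2)


class TestSoftTissueMask:
    def test_hu_window_inclusive_bounds(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [200.0, -150.0, 180.0, -151.0]
        mask = RegionMask(np.ones((1, 1, 4), dtype=bool), (1, 1, 1))
        out = soft_tissue_mask(ct(vals), mask)
        np.testing.assert_array_equal(out.values[0, 0], [False, True, True, False])

    def test_all_soft_tissue_unchanged_and_idempotent(self):
        mask = RegionMask(np.ones((3, 3, 3), dtype=bool), (1, 1, 1))
        img = ct(np.zeros((3, 3, 3)))
        once = soft_tissue_mask(img, mask)
        np.testing.assert_array_equal(once.values, mask.values)
        twice = soft_tissue_mask(img, once)
        np.testing.assert_array_equal(twice.values, once.values)

    def test_empty_result_raises(self):
        mask = RegionMask(np.ones((2, 2, 2), dtype=bool), (1, 1, 1))
        with pytest.raises(EmptyRegionError):
            soft_tissue_mask(ct(np.full((2, 2, 2), 999.0)), mask)


class TestSUV:
    def test_body_weight_formula(self):
        pet = VolumetricImage(np.full((2, 2, 2), 5000.0), (1, 1, 1), "PET", "Bq/mL")
        acq = AcquisitionInfo(injected_dose_bq=3.5e8, body_weight_g=70000)
        out = compute_suv(pet, acq)
        assert out.units == "SUV"
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_activity_and_linearity_in_weight(self):
        vals = np.array([[[0.0, 2500.0]]])
        pet = VolumetricImage(vals, (1, 1, 1), "PET", "Bq/mL")
        a = compute_suv(pet, AcquisitionInfo(3.5e8, 70000))
        b = compute_suv(pet, AcquisitionInfo(3.5e8, 140000))
        assert a.values[0, 0, 0] == 0.0
        np.testing.assert_allclose(b.values, 2 * a.values)

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AcquisitionInfo(injected_dose_bq=0.0, body_weight_g=70000)
        with pytest.raises(InvalidArgumentError):
            AcquisitionInfo(injected_dose_bq=3.5e8, body_weight_g=-1)


def suv_image(vals):
    return VolumetricImage(np.asarray(vals, dtype=float), (1, 1, 1), "PET", "SUV")


class TestSUVThreshold:
    def test_uniform_above_threshold_gives_full_volume(self):
        out = suv_threshold_region(suv_image(np.full((3, 3, 3), 3.0)), 2.5)
        assert out.n_foreground == 27

    def test_uniform_below_threshold_raises(self):
        with pytest.raises(EmptyRegionError):
            suv_threshold_region(suv_image(np.full((3, 3, 3), 1.0)), 2.5)

    def test_seed_restricts_to_connected_component(self):
        # two disjoint supra-threshold blobs; brute-force 26-connectivity
        # flood fill from the seed is the oracle
        vals = np.ones((8, 8, 8))
        vals[1:3, 1:3, 1:3] = 4.0
        vals[5:8, 5:8, 5:8] = 4.0
        seed = np.zeros((8, 8, 8), dtype=bool)
        seed[2, 2, 2] = True
        out = suv_threshold_region(
            suv_image(vals), 2.5, RegionMask(seed, (1, 1, 1))
        )
        # oracle: BFS over 26-neighbourhood from the seed voxel
        supra = vals >= 2.5
        frontier = [(2, 2, 2)]
        reach = {(2, 2, 2)}
        while frontier:
            cz, cy, cx = frontier.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        p = (cz + dz, cy + dy, cx + dx)
                        if (
                            p not in reach
                            and all(0 <= v < 8 for v in p)
                            and supra[p]
                        ):
                            reach.add(p)
                            frontier.append(p)
        expected = np.zeros((8, 8, 8), dtype=bool)
        for p in reach:
            expected[p] = True
        np.testing.assert_array_equal(out.values, expected)


def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    img = VolumetricImage(rng.normal(size=(5, 6, 7)), (1.0, 1.5, 2.0), "CT", "HU")
    mask = RegionMask(rng.random((5, 6, 7)) > 0.4, (1.0, 1.5, 2.0))
    save_image(img, tmp_path / "img.nii.gz")
    save_mask(mask, tmp_path / "mask.nii.gz")
    img2 = load_image(tmp_path / "img.nii.gz", "CT", "HU")
    mask2 = load_mask(tmp_path / "mask.nii.gz")
    np.testing.assert_allclose(img2.values, img.values, atol=1e-6)
    np.testing.assert_allclose(img2.spacing, img.spacing, atol=1e-6)
    np.testing.assert_array_equal(mask2.values, mask.values)


def test_image_invariants_enforced():
    with pytest.raises(InvalidArgumentError):
        VolumetricImage(np.zeros((2, 2, 2)), (1, 0, 1), "CT", "HU")
    with pytest.raises(InvalidArgumentError):
        VolumetricImage(np.zeros((2, 2, 2)), (1, 1, 1), "CT", "SUV")
    with pytest.raises(InvalidArgumentError):
        VolumetricImage(np.zeros((2, 2)), (1, 1, 1), "PET", "SUV")
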