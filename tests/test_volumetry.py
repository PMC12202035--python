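"""Subtraction volumetry: registration, normalization, segmentation, volumes."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cedkit.phantom import PhantomSpec, generate_phantom
from cedkit.volumetry import (
    BinaryMask,
    ImageVolume,
    RegistrationError,
    SegmentationError,
    dice,
    load_nifti,
    mask_volume_cm3,
    normalize_post,
    register_rigid,
    resample_image,
    save_nifti,
    segment_reference,
    segment_tumor,
    segment_vd,
)


def full_roi(vol: ImageVolume) -> BinaryMask:
    return BinaryMask(np.ones(vol.shape, dtype=bool), vol.spacing_mm, vol.origin_mm)


def run_chain(case, k_sigma=3.0, min_component_cm3=0.05):
    post_norm, norm = normalize_post(case.pre_t1, case.post_t1, case.reference_mask)
    return segment_vd(
        case.pre_t1,
        post_norm,
        full_roi(case.pre_t1),
        residual_sigma=norm.residual_sigma,
        k_sigma=k_sigma,
        min_component_cm3=min_component_cm3,
    )


class TestRegistration:
    def test_identity_on_identical_inputs(self, noiseless_case):
        t = register_rigid(noiseless_case.pre_t1, noiseless_case.pre_t1)
        assert t.is_identity(atol=1e-6)

    def test_recovers_integer_voxel_shift(self, noiseless_case):
        fixed = noiseless_case.pre_t1
        moving = ImageVolume(
            np.roll(fixed.voxels, 2, axis=0), fixed.spacing_mm, fixed.origin_mm
        )
        t = register_rigid(fixed, moving)
        assert abs(t.translation_mm[0] - 2.0 * fixed.spacing_mm[0]) < 0.1
        assert abs(t.translation_mm[1]) < 0.1 and abs(t.translation_mm[2]) < 0.1

    def test_recovers_subvoxel_shift_under_noise(self, small_spec):
        case = generate_phantom(
            dataclasses.replace(small_spec, noise_sigma=0.0), seed=5
        )
        fixed = case.pre_t1
        true_shift = (1.5, -1.0, 0.5)  # mm
        shifted = ndimage.shift(fixed.voxels, true_shift, order=1, mode="nearest")
        rng = np.random.default_rng(0)
        shifted = shifted + rng.normal(0, 2.0, shifted.shape)  # 2% of signal
        moving = ImageVolume(shifted, fixed.spacing_mm, fixed.origin_mm)
        t = register_rigid(fixed, moving)
        assert np.all(np.abs(np.asarray(t.translation_mm) - true_shift) < 0.5)

    def test_disjoint_volumes_rejected(self, noiseless_case):
        fixed = noiseless_case.pre_t1
        far = ImageVolume(fixed.voxels, fixed.spacing_mm, (1000.0, 1000.0, 1000.0))
        with pytest.raises(RegistrationError):
            register_rigid(fixed, far)


class TestReferenceSegmentation:
    def test_recovers_reference_structure(self, noiseless_case):
        case = noiseless_case
        seed_mm = case.spec.reference_center_mm
        mask = segment_reference(case.pre_t1, seed_mm, (105.0, 195.0))
        assert dice(mask, case.reference_mask) > 0.99

    def test_window_excluding_seed_rejected(self, noiseless_case):
        with pytest.raises(SegmentationError):
            segment_reference(
                noiseless_case.pre_t1,
                noiseless_case.spec.reference_center_mm,
                (300.0, 400.0),
            )

    def test_seed_inside_infusate_is_caller_error(self, noiseless_case):
        """The reference must be uninfused: a seed in vd_truth violates the contract."""
        case = noiseless_case
        seed_mm = case.spec.infusate_center_mm
        mask = segment_reference(case.pre_t1, seed_mm, (80.0, 120.0))
        assert np.any(mask.voxels & case.vd_truth.voxels)  # detectable violation


class TestNormalization:
    def test_inverts_known_affine_map(self, noiseless_case):
        """post = 1.2 pre + 30 exactly -> scale 1/1.2, offset -25, post_norm == pre."""
        pre = noiseless_case.pre_t1
        post = ImageVolume(1.2 * pre.voxels + 30.0, pre.spacing_mm, pre.origin_mm)
        post_norm, norm = normalize_post(pre, post, noiseless_case.reference_mask)
        assert norm.scale == pytest.approx(1.0 / 1.2, rel=1e-9)
        assert norm.offset == pytest.approx(-25.0, rel=1e-9)
        assert np.allclose(post_norm.voxels, pre.voxels, atol=1e-9)

    def test_identity_map(self, noiseless_case):
        pre = noiseless_case.pre_t1
        _, norm = normalize_post(pre, pre, noiseless_case.reference_mask)
        assert norm.scale == pytest.approx(1.0)
        assert norm.offset == pytest.approx(0.0, abs=1e-9)
        assert norm.residual_sigma == pytest.approx(0.0, abs=1e-9)

    def test_moments_match_inside_reference(self, small_spec):
        case = generate_phantom(small_spec, seed=2)
        post_norm, _ = normalize_post(case.pre_t1, case.post_t1, case.reference_mask)
        ref = case.reference_mask.voxels
        assert post_norm.voxels[ref].mean() == pytest.approx(
            case.pre_t1.voxels[ref].mean(), rel=1e-9
        )
        assert post_norm.voxels[ref].std() == pytest.approx(
            case.pre_t1.voxels[ref].std(), rel=1e-9
        )

    def test_drift_recovery_outside_reference(self, noiseless_case):
        """Normalized difference is ~0 outside vd_truth and ~delta/scale inside."""
        case = noiseless_case
        post_norm, _ = normalize_post(case.pre_t1, case.post_t1, case.reference_mask)
        diff = post_norm.voxels - case.pre_t1.voxels
        outside = ~case.vd_truth.voxels
        assert np.abs(diff[outside]).max() < 1e-9
        inside = case.vd_truth.voxels
        expected = case.spec.delta_intensity / case.spec.drift_scale
        assert np.allclose(diff[inside], expected, atol=1e-9)

    def test_degenerate_reference_rejected(self, noiseless_case):
        pre = noiseless_case.pre_t1
        flat = ImageVolume(np.full(pre.shape, 7.0), pre.spacing_mm, pre.origin_mm)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_post(pre, flat, noiseless_case.reference_mask)


class TestVdSegmentation:
    def test_zero_difference_gives_empty_mask(self, noiseless_case):
        pre = noiseless_case.pre_t1
        mask = segment_vd(pre, pre, full_roi(pre), residual_sigma=0.0)
        assert mask.count() == 0

    def test_noiseless_chain_recovers_truth_exactly(self, noiseless_case):
        mask = run_chain(noiseless_case)
        assert np.array_equal(mask.voxels, noiseless_case.vd_truth.voxels)

    def test_noisy_chain_dice_and_volume(self, small_spec):
        """SNR 10 (delta 50, sigma 5): Dice >= 0.90, |volume error| <= 5%."""
        case = generate_phantom(small_spec, seed=17)
        mask = run_chain(case)
        assert dice(mask, case.vd_truth) >= 0.90
        truth = mask_volume_cm3(case.vd_truth)
        assert abs(mask_volume_cm3(mask) - truth) / truth <= 0.05

    def test_affine_drift_invariance(self, noiseless_case):
        """segment_vd output is voxel-identical under any affine post corruption."""
        case = noiseless_case
        baseline = run_chain(case)
        for a in (0.8, 1.0, 1.2):
            for b in (-30.0, 0.0, 30.0):
                corrupted = dataclasses.replace(
                    case,
                    post_t1=ImageVolume(
                        a * case.post_t1.voxels + b,
                        case.post_t1.spacing_mm,
                        case.post_t1.origin_mm,
                    ),
                )
                mask = run_chain(corrupted)
                assert np.array_equal(mask.voxels, baseline.voxels)

    def test_k_sigma_monotonicity(self, small_spec):
        case = generate_phantom(small_spec, seed=23)
        post_norm, norm = normalize_post(case.pre_t1, case.post_t1, case.reference_mask)
        roi = full_roi(case.pre_t1)
        prev = None
        for k in (1.0, 2.0, 3.0, 5.0):
            mask = segment_vd(
                case.pre_t1, post_norm, roi,
                residual_sigma=norm.residual_sigma, k_sigma=k, min_component_cm3=0.0,
            )
            if prev is not None:
                assert np.all(prev.voxels | ~mask.voxels)  # mask subset of prev
            prev = mask

    def test_mask_subset_of_roi(self, small_spec):
        case = generate_phantom(small_spec, seed=29)
        roi_vox = np.zeros(case.pre_t1.shape, dtype=bool)
        roi_vox[10:22, 10:22, 10:22] = True
        roi = BinaryMask(roi_vox, case.pre_t1.spacing_mm, case.pre_t1.origin_mm)
        post_norm, norm = normalize_post(case.pre_t1, case.post_t1, case.reference_mask)
        mask = segment_vd(
            case.pre_t1, post_norm, roi, residual_sigma=norm.residual_sigma
        )
        assert not np.any(mask.voxels & ~roi.voxels)


class TestVolumesAndTumor:
    def test_empty_mask_volume(self):
        m = BinaryMask(np.zeros((5, 5, 5), dtype=bool), (1.0, 1.0, 1.0))
        assert mask_volume_cm3(m) == 0.0

    def test_unit_conversion(self):
        v = np.zeros((20, 20, 20), dtype=bool)
        v[:10, :10, :10] = True  # 1000 voxels at 1 mm^3
        assert mask_volume_cm3(BinaryMask(v, (1.0, 1.0, 1.0))) == 1.0

    def test_anisotropic_voxels(self):
        v = np.ones((10, 10, 10), dtype=bool)
        assert mask_volume_cm3(BinaryMask(v, (0.5, 1.0, 2.0))) == 1.0

    def test_tumor_segmentation_recovers_truth(self, noiseless_case):
        case = noiseless_case
        mask = segment_tumor(case.flair, case.spec.tumor_center_mm, 150.0)
        assert dice(mask, case.tumor_truth) > 0.99

    def test_threshold_above_all_intensities_rejected(self, noiseless_case):
        with pytest.raises(SegmentationError):
            segment_tumor(noiseless_case.flair, noiseless_case.spec.tumor_center_mm, 250.0)

    def test_interior_cyst_included_by_hole_filling(self):
        flair = np.full((24, 24, 24), 100.0)
        flair[6:18, 6:18, 6:18] = 200.0
        flair[10:14, 10:14, 10:14] = 80.0  # dark cyst inside the tumor
        vol = ImageVolume(flair, (1.0, 1.0, 1.0))
        mask = segment_tumor(vol, (7.0, 7.0, 7.0), 150.0)
        assert mask.voxels[12, 12, 12]  # cyst voxel included
        assert mask.count() == 12**3


def test_nifti_roundtrip(tmp_path, noiseless_case):
    case = noiseless_case
    p_img, p_msk = tmp_path / "pre.nii.gz", tmp_path / "vd.nii.gz"
    save_nifti(case.pre_t1, p_img)
    save_nifti(case.vd_truth, p_msk)
    img = load_nifti(p_img)
    msk = load_nifti(p_msk, as_mask=True)
    assert img.spacing_mm == case.pre_t1.spacing_mm
    assert np.allclose(img.voxels, case.pre_t1.voxels, atol=1e-4)
    assert np.array_equal(msk.voxels, case.vd_truth.voxels)


def test_resample_between_lattices(noiseless_case):
    """Downsampled-then-queried image keeps interior intensities."""
    src = noiseless_case.pre_t1
    coarse = ImageVolume(
        np.zeros((16, 16, 16)), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0)
    )
    out = resample_image(src, coarse)
    assert out.shape == (16, 16, 16)
    assert out.voxels.min() >= src.voxels.min() - 1e-6
    assert out.voxels.max() <= src.voxels.max() + 1e-6
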