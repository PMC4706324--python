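"""MIPs, NMSE/PSNR/SSIM, forced-keypoint SIFT distance, CNR, slice NMSE."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import csmra
from csmra.errors import InvalidArgumentError, NoKeypointsError
from csmra.metrics import (
    SSIMConfig,
    cnr_artery_parenchyma,
    evaluate_all,
    mip,
    mse,
    nmse,
    psnr,
    sift_forced_distance,
    slice_nmse,
    ssim,
)

from _oracles import ssim_loop


@pytest.fixture(scope="module")
def phantom_mip():
    """Masked, normalized reference MIP of a mid-size phantom (keypoint-rich)."""
    vol, masks = csmra.generate_phantom(shape=(96, 96, 48), seed=1)
    img = mip(vol, mask=masks.brain).data
    return img / img.max()


class TestMip:
    def test_constant_volume_projects_to_constant(self):
        m = mip(np.full((8, 8, 8), 2.5))
        assert np.all(m.data == 2.5)
        assert m.shape == (8, 8)

    def test_all_false_mask_gives_zero(self):
        m = mip(np.random.default_rng(0).random((8, 8, 8)), mask=np.zeros((8, 8, 8), bool))
        assert np.all(m.data == 0)

    def test_single_bright_voxel_lands_in_plane_position(self):
        v = np.zeros((8, 8, 8))
        v[3, 5, 2] = 9.0
        m = mip(v, axis="craniocaudal")
        assert m.data[3, 5] == 9.0
        assert m.data.sum() == 9.0

    def test_unknown_axis_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mip(np.zeros((8, 8, 8)), axis="diagonal")

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mip(np.zeros((8, 8, 8)), mask=np.ones((4, 4, 4), bool))


class TestNmsePsnr:
    def test_identical_images_zero_nmse(self):
        x = np.random.default_rng(1).random((8, 8))
        assert nmse(x, x) == 0.0

    def test_zero_reconstruction_gives_one(self):
        x = np.random.default_rng(2).random((8, 8)) + 0.1
        assert nmse(x, np.zeros_like(x)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        ref = np.ones((2, 2))
        rec = np.array([[1.0, 1.0], [1.0, 0.0]])
        assert mse(ref, rec) == pytest.approx(0.25)
        assert nmse(ref, rec) == pytest.approx(0.25)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            nmse(np.zeros((4, 4)), np.ones((4, 4)))

    def test_psnr_closed_forms(self):
        ref = np.zeros((10, 10))
        rec = np.full((10, 10), 0.1)  # MSE = 0.01
        assert psnr(ref, rec, max_value=1.0) == pytest.approx(20.0, abs=1e-9)
        rec255 = np.full((10, 10), 255.0)
        assert psnr(np.zeros((10, 10)), rec255, max_value=255.0) == pytest.approx(0.0)

    def test_identical_images_infinite_psnr(self):
        x = np.random.default_rng(3).random((8, 8))
        assert psnr(x, x) == math.inf

    def test_psnr_mse_consistency(self):
        rng = np.random.default_rng(4)
        x, y = rng.random((12, 12)), rng.random((12, 12))
        p = psnr(x, y, max_value=1.0)
        assert abs(10 ** (-p / 10.0) - mse(x, y)) < 1e-10


class TestSsim:
    def test_identical_images_give_exactly_one(self):
        x = np.random.default_rng(5).random((16, 16))
        assert ssim(x, x) == 1.0

    def test_negated_image_scores_nonpositive(self):
        # alternating-sign pattern: every 8x8 window has zero mean and unit
        # variance, so the (negative) covariance term drives the score
        i = np.arange(16)
        x = ((-1.0) ** i)[:, None] * np.ones((16, 16))
        assert ssim(x, -x) < 0.0

    def test_sliding_equals_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        x, y = rng.random((16, 16)), rng.random((16, 16))
        cfg = SSIMConfig(window=8, dynamic_range=1.0)
        assert abs(ssim(x, y, cfg) - ssim_loop(x, y, 8, cfg.c1, cfg.c2)) < 1e-12

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ssim(np.zeros((4, 4)), np.zeros((4, 4)))


class TestSiftForcedDistance:
    def test_identical_images_distance_zero(self, phantom_mip):
        d, kps = sift_forced_distance(phantom_mip, phantom_mip)
        assert d == 0.0
        assert len(kps) >= 1

    def test_constant_offset_invariance(self, phantom_mip):
        d, _ = sift_forced_distance(phantom_mip, phantom_mip + 0.37)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_blur_increases_distance(self, phantom_mip):
        blurred = gaussian_filter(phantom_mip, 4.0)
        d_blur, _ = sift_forced_distance(phantom_mip, blurred)
        d_same, _ = sift_forced_distance(phantom_mip, phantom_mip)
        assert d_blur > d_same

    def test_flat_reference_has_no_keypoints(self):
        with pytest.raises(NoKeypointsError):
            sift_forced_distance(np.full((64, 64), 0.5), np.zeros((64, 64)))

    def test_keypoints_and_descriptors_aligned(self, phantom_mip):
        _, kps = sift_forced_distance(phantom_mip, phantom_mip)
        assert len(kps.locations) == len(kps.descriptors)
        assert kps.descriptors.shape[1] == 128


class TestCnr:
    def _masks(self):
        brain = np.zeros((8, 8, 8), bool)
        brain[1:7, 1:7, 1:7] = True
        arterial = np.zeros((8, 8, 8), bool)
        arterial[3:5, 3:5, 3:5] = True
        return csmra.MaskSet(brain, arterial, brain & ~arterial)

    def test_constructed_value(self):
        masks = self._masks()
        rec = np.where(masks.arterial, 3.0, 1.0)
        rng = np.random.default_rng(8)
        noise = rng.standard_normal(rec.shape)
        par = noise[masks.parenchymal]
        noise_sd = par.std(ddof=0)
        ref = rec + noise / noise_sd  # (ref - rec) has unit SD on parenchyma
        assert cnr_artery_parenchyma(rec, ref, masks) == pytest.approx(2.0)

    def test_identical_volumes_infinite_with_warning(self):
        masks = self._masks()
        rec = np.where(masks.arterial, 3.0, 1.0)
        with pytest.warns(RuntimeWarning):
            assert cnr_artery_parenchyma(rec, rec, masks) == math.inf

    def test_joint_scaling_invariance(self):
        masks = self._masks()
        rng = np.random.default_rng(9)
        rec = np.where(masks.arterial, 3.0, 1.0) + 0.1 * rng.random((8, 8, 8))
        ref = rec + 0.2 * rng.standard_normal((8, 8, 8))
        c1 = cnr_artery_parenchyma(rec, ref, masks)
        c2 = cnr_artery_parenchyma(7.3 * rec, 7.3 * ref, masks)
        assert c1 == pytest.approx(c2)


class TestSliceNmse:
    def test_identical_volumes_zero(self):
        v = np.random.default_rng(10).random((8, 8, 4))
        assert slice_nmse(v, v) == 0.0

    def test_single_slice_equals_2d_nmse(self):
        rng = np.random.default_rng(11)
        ref = rng.random((8, 8, 1))
        rec = rng.random((8, 8, 1))
        assert slice_nmse(ref, rec) == pytest.approx(nmse(ref[:, :, 0], rec[:, :, 0]))

    def test_four_slice_average(self):
        rng = np.random.default_rng(12)
        ref = rng.random((8, 8, 4)) + 0.5
        rec = np.empty_like(ref)
        for k, t in enumerate([0.0, 0.2, 0.4, 0.6]):
            rec[:, :, k] = ref[:, :, k] * (1.0 - np.sqrt(t))  # slice NMSE = t
        assert slice_nmse(ref, rec) == pytest.approx(0.3)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            slice_nmse(np.zeros((8, 8, 2)), np.ones((8, 8, 2)))


class TestMaskRestriction:
    def test_outside_brain_changes_masked_metrics_by_exactly_zero(self):
        vol, masks = csmra.generate_phantom(shape=(64, 64, 32), seed=6)
        rng = np.random.default_rng(13)
        rec = vol.data * (1.0 + 0.05 * rng.standard_normal(vol.shape))
        rec = np.abs(rec)
        base = evaluate_all(vol, rec, masks)
        tampered = rec.copy()
        tampered[~masks.brain] += rng.random((~masks.brain).sum()) * 5.0
        out = evaluate_all(vol, tampered, masks)
        for key in ("nmse_masked", "psnr_masked", "ssim_masked", "sift_dist_masked", "cnr"):
            assert out[key] == base[key], key
        assert out["nmse"] != base["nmse"]  # unmasked metrics do see the change

    def test_evaluate_all_reports_full_metric_set(self):
        vol, masks = csmra.generate_phantom(shape=(64, 64, 32), seed=6)
        out = evaluate_all(vol, vol.data * 0.98, masks)
        assert set(csmra.METRIC_DIRECTIONS) <= set(out)
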