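"""Posture pipeline: binarization, endpoints, centerline, curvature, kymograph."""

import numpy as np
import pytest

import wormbend as wb
from wormbend import posture
from wormbend.errors import (
    EndpointError,
    OrientationError,
    QualityError,
    SegmentationError,
)
from skimage.draw import disk


def _render(curvature_row, width=None, shape=(384, 384), mpp=0.004):
    cl = wb.centerline_from_curvature(curvature_row, 1.0)
    return wb.render_worm_mask(cl, width, shape, mpp), cl


class TestBinarize:
    def test_fixed_threshold_is_idempotent_on_masks(self, straight_worm_frame):
        frame, _ = straight_worm_frame
        out = posture.binarize_frame(frame.mask.astype(float), "fixed", 0.5,
                                     mm_per_px=frame.mm_per_px)
        assert np.array_equal(out.mask, frame.mask)

    def test_all_black_image_raises(self):
        with pytest.raises(SegmentationError):
            posture.binarize_frame(np.zeros((64, 64)), "fixed", 0.5)

    def test_otsu_recovers_mask_under_pixel_noise(self, straight_worm_frame):
        # Gaussian noise at 10% of dynamic range: Jaccard >= 0.95 vs truth
        frame, _ = straight_worm_frame
        rng = np.random.default_rng(0)
        img = frame.mask.astype(float) + rng.normal(0, 0.1, frame.mask.shape)
        out = posture.binarize_frame(img, "otsu", mm_per_px=frame.mm_per_px)
        inter = (out.mask & frame.mask).sum()
        union = (out.mask | frame.mask).sum()
        assert inter / union >= 0.95


class TestEndpoints:
    def test_straight_stadium_tips(self, straight_worm_frame):
        frame, cl = straight_worm_frame
        e1, e2 = posture.find_endpoints(frame)
        off = frame.mask.shape[0] // 2 * frame.mm_per_px
        tips = cl.points[[0, -1]] + off
        d = min(
            np.linalg.norm(e1 - tips[0]) + np.linalg.norm(e2 - tips[1]),
            np.linalg.norm(e1 - tips[1]) + np.linalg.norm(e2 - tips[0]),
        )
        assert d / 2 <= 2 * frame.mm_per_px  # within 2 px each on average

    def test_disc_has_no_endpoints(self):
        mask = np.zeros((128, 128), dtype=bool)
        rr, cc = disk((64, 64), 40)
        mask[rr, cc] = True
        with pytest.raises(EndpointError):
            posture.find_endpoints(wb.WormFrame(mask=mask, mm_per_px=0.004))

    def test_u_shaped_worm_tips_beat_bend_apex(self):
        # half-circle posture: the outer bend apex must not win over the tips
        frame, cl = _render(np.full(100, np.pi))
        e1, e2 = posture.find_endpoints(frame)
        off = frame.mask.shape[0] // 2 * frame.mm_per_px
        tips = cl.points[[0, -1]] + off
        d = min(
            np.linalg.norm(e1 - tips[0]) + np.linalg.norm(e2 - tips[1]),
            np.linalg.norm(e1 - tips[1]) + np.linalg.norm(e2 - tips[0]),
        )
        assert d / 2 <= 3 * frame.mm_per_px


class TestExtractCenterline:
    def _centerline(self, frame):
        e1, e2 = posture.find_endpoints(frame)
        return posture.extract_centerline(frame, e1, e2)

    def test_straight_worm_is_collinear(self, straight_worm_frame):
        frame, _ = straight_worm_frame
        cl = self._centerline(frame)
        y = cl.points[:, 1]
        assert np.ptp(y) < 1.0 * frame.mm_per_px

    def test_rotation_equivariance(self):
        # a rigidly rotated worm yields the rotated centerline: arclength
        # unchanged within 1%, geometry congruent within ~a pixel
        row = 2.0 * np.sin(2 * np.pi * (np.arange(100) + 0.5) / 100)
        frame, _ = _render(row)
        cl = self._centerline(frame)
        rot = np.radians(37.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        cl_rot_truth = wb.Centerline(points=wb.centerline_from_curvature(row, 1.0).points @ R.T)
        frame2 = wb.render_worm_mask(cl_rot_truth, None, (384, 384), 0.004)
        cl2 = self._centerline(frame2)
        assert cl2.arclength == pytest.approx(cl.arclength, rel=0.01)
        expect = (cl.points - cl.points.mean(axis=0)) @ R.T
        got = cl2.points - cl2.points.mean(axis=0)
        rms = min(
            np.sqrt(np.mean((got - expect) ** 2)),
            np.sqrt(np.mean((got[::-1] * -1 + 2 * 0 - expect) ** 2)),  # reversed order
            np.sqrt(np.mean((got[::-1] - expect) ** 2)),
        )
        assert rms < 1.5 * frame.mm_per_px
        # and the curvature profile agrees away from the tips
        k1 = posture.compute_curvature(cl)
        k2 = posture.compute_curvature(cl2)
        if np.corrcoef(k1, k2)[0, 1] < np.corrcoef(k1, -k2[::-1])[0, 1]:
            k2 = -k2[::-1]
        central = slice(5, 95)
        rmse = np.sqrt(np.mean((k1[central] - k2[central]) ** 2))
        assert rmse < 0.05 * np.abs(k1).max() + 0.05

    def test_half_circle_arclength(self):
        frame, cl_true = _render(np.full(100, np.pi))
        cl = self._centerline(frame)
        assert cl.arclength == pytest.approx(cl_true.arclength, rel=0.02)


class TestComputeCurvature:
    def test_straight_centerline_is_zero(self):
        cl = wb.centerline_from_curvature(np.zeros(100), 1.0)
        assert np.abs(posture.compute_curvature(cl)).max() < 1e-6

    def test_circular_arc_constant_curvature(self):
        # arc with L = pi R -> kappa * L = pi everywhere, within 2%
        cl = wb.centerline_from_curvature(np.full(100, np.pi), 1.0)
        k = posture.compute_curvature(cl)
        assert np.allclose(k, np.pi, rtol=0.02)

    def test_mirror_flip_negates_curvature(self):
        row = 2.5 * np.sin(2 * np.pi * (np.arange(100) + 0.5) / 100 * 1.3)
        cl = wb.centerline_from_curvature(row, 1.0)
        mirrored = wb.Centerline(points=cl.points * np.array([1.0, -1.0]))
        k = posture.compute_curvature(cl)
        km = posture.compute_curvature(mirrored)
        assert np.allclose(km, -k, atol=1e-9)

    def test_ventral_sign_flag_flips_sign(self):
        row = np.full(100, 1.0)
        cl = wb.centerline_from_curvature(row, 1.0)
        k1 = posture.compute_curvature(cl, ventral_sign=1)
        k2 = posture.compute_curvature(cl, ventral_sign=-1)
        assert np.allclose(k1, -k2)


class TestBuildKymograph:
    def test_shape_and_no_failures_on_clean_movie(self, movie_and_truth,
                                                  recovered_kymograph):
        frames, _ = movie_and_truth
        kymo, _ = recovered_kymograph
        assert kymo.values.shape == (len(frames), 100)
        assert kymo.failed_frames == []
        assert kymo.frame_rate == pytest.approx(5.0)

    def test_pipeline_closure_nrmse_below_ten_percent(self, movie_and_truth,
                                                      recovered_kymograph):
        _, gt = movie_and_truth
        kymo, _ = recovered_kymograph
        err = kymo.values - gt.kymograph.values
        nrmse = np.sqrt(np.nanmean(err ** 2)) / np.sqrt(np.mean(gt.kymograph.values ** 2))
        assert nrmse < 0.10

    def test_failed_frames_are_nan_not_zero(self, movie_and_truth):
        frames, _ = movie_and_truth
        frames = list(frames[:12])
        bad = np.zeros_like(frames[0].mask)
        rr, cc = disk((192, 192), 40)
        bad[rr, cc] = True  # a disc defeats endpoint detection
        frames[5] = wb.WormFrame(mask=bad, timestamp=frames[5].timestamp,
                                 mm_per_px=frames[5].mm_per_px)
        kymo, cls = posture.build_kymograph(frames)
        assert kymo.failed_frames == [5]
        assert np.isnan(kymo.values[5]).all()
        assert cls[5] is None

    def test_too_many_failures_raises_quality_error(self, movie_and_truth):
        frames, _ = movie_and_truth
        frames = list(frames[:10])
        bad = np.zeros_like(frames[0].mask)
        rr, cc = disk((192, 192), 40)
        bad[rr, cc] = True
        for i in (2, 4, 6):
            frames[i] = wb.WormFrame(mask=bad, timestamp=frames[i].timestamp,
                                     mm_per_px=frames[i].mm_per_px)
        with pytest.raises(QualityError):
            posture.build_kymograph(frames)

    def test_arclength_conserved_across_movie(self, recovered_kymograph):
        kymo, _ = recovered_kymograph
        lengths = kymo.body_lengths[np.isfinite(kymo.body_lengths)]
        assert lengths.max() / lengths.min() - 1 < 0.03

    def test_translation_leaves_kymograph_unchanged(self, movie_and_truth,
                                                    recovered_kymograph):
        frames, _ = movie_and_truth
        kymo, _ = recovered_kymograph
        shifted = [
            wb.WormFrame(mask=np.roll(f.mask, (7, -9), axis=(0, 1)),
                         timestamp=f.timestamp, mm_per_px=f.mm_per_px)
            for f in frames[:15]
        ]
        kymo2, _ = posture.build_kymograph(shifted)
        a, b = kymo.values[:15], kymo2.values
        rmse = np.sqrt(np.nanmean((a - b) ** 2)) / np.sqrt(np.nanmean(a ** 2))
        assert rmse < 0.02


class TestHeadTailAssignment:
    def test_wave_orients_head_first(self, noisy_wave_kymograph):
        assert posture.assign_head_tail(noisy_wave_kymograph) is True

    def test_time_reversal_flips_assignment(self, noisy_wave_kymograph):
        k = noisy_wave_kymograph
        rev = wb.CurvatureKymograph(values=k.values[::-1].copy(),
                                    frame_rate=k.frame_rate)
        assert posture.assign_head_tail(rev) is False

    def test_static_worm_raises_orientation_error(self):
        k = wb.CurvatureKymograph(values=np.ones((50, 100)), frame_rate=5.0)
        with pytest.raises(OrientationError):
            posture.assign_head_tail(k)

    def test_manual_override_honored(self, noisy_wave_kymograph):
        assert posture.assign_head_tail(noisy_wave_kymograph, override="last") is False

    def test_orientation_correct_across_noisy_replicates(self):
        hits = 0
        for seed in range(10):
            p = wb.WaveParams(curvature_amplitude=3.0, duration=20.0,
                              noise_sd=1.0, seed=seed)
            hits += posture.assign_head_tail(wb.make_curvature_wave(p)) is True
        assert hits >= 9

    def test_recovered_movie_head_matches_ground_truth(self, movie_and_truth,
                                                       recovered_kymograph):
        _, gt = movie_and_truth
        kymo, _ = recovered_kymograph
        # correlation with truth must beat correlation with the flipped truth
        truth = gt.kymograph.values
        flipped = -truth[:, ::-1]
        c_ok = np.corrcoef(kymo.values.ravel(), truth.ravel())[0, 1]
        c_flip = np.corrcoef(kymo.values.ravel(), flipped.ravel())[0, 1]
        assert c_ok > 0.95 > c_flip
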