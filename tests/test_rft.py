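"""Bout kinematics, the RFT efficiency curve, the force-balance oracle and the
drag-ratio fit."""

import numpy as np
import pandas as pd
import pytest

import wormbend as wb
from wormbend import rft
from wormbend.errors import ConfigurationError, DataError, WaveSpeedError


def wave_kymo(**kw):
    defaults = dict(curvature_amplitude=3.0, duration=30.0, frame_rate=5.0)
    defaults.update(kw)
    return wb.make_curvature_wave(wb.WaveParams(**defaults))


class TestSegmentBouts:
    def test_all_forward_movie_is_one_bout(self):
        k = wave_kymo(duration=15.0)
        bouts = rft.segment_bouts(k, min_duration=10.0)
        assert len(bouts) == 1
        assert bouts[0].start == 0 and bouts[0].stop == k.n_frames

    def test_flagged_reversal_splits_into_two_bouts(self):
        k = wave_kymo(duration=14.0)
        flags = np.zeros(k.n_frames, bool)
        flags[30:40] = True  # 2 s reversal in the middle
        bouts = rft.segment_bouts(k, min_duration=5.0, reversal_flags=flags)
        assert len(bouts) == 2

    def test_no_bout_overlaps_excluded_frames(self):
        rng = np.random.default_rng(0)
        k = wave_kymo(duration=60.0)
        for _ in range(20):
            flags = np.zeros(k.n_frames, bool)
            starts = rng.integers(0, k.n_frames - 5, size=4)
            for s in starts:
                flags[s:s + rng.integers(1, 10)] = True
            for b in rft.segment_bouts(k, min_duration=3.0, reversal_flags=flags):
                assert not flags[b.start:b.stop].any()

    def test_turn_frames_excluded_by_mean_curvature(self):
        k = wave_kymo(duration=20.0)
        k.values[40:45] += 2.0  # |mean body curvature| > pi/2 -> turn
        bouts = rft.segment_bouts(k, min_duration=5.0)
        for b in bouts:
            assert not (b.start <= 40 < b.stop)

    def test_empty_result_warns(self):
        k = wave_kymo(duration=4.0)
        with pytest.warns(UserWarning, match="no qualifying"):
            assert rft.segment_bouts(k, min_duration=10.0) == []


class TestActualSpeed:
    def test_rigid_translation_speed(self):
        t = np.arange(50) / 5.0
        track = np.stack([0.1 * t, np.zeros_like(t)], axis=1)
        b = wb.Bout(start=0, stop=50, frame_rate=5.0)
        assert rft.actual_speed(b, track) == pytest.approx(0.1, rel=1e-9)

    def test_stationary_undulation_is_zero(self):
        track = np.zeros((50, 2))
        b = wb.Bout(start=0, stop=50, frame_rate=5.0)
        assert rft.actual_speed(b, track) == 0.0


class TestWaveSpeed:
    def test_matches_lambda_times_frequency(self):
        # lambda = 1 body length, f = 1 Hz, L = 1 mm -> V_w = 1 mm/s within 3%
        assert rft.wave_speed(wave_kymo()) == pytest.approx(1.0, rel=0.03)

    def test_halving_wavelength_halves_speed(self):
        v1 = rft.wave_speed(wave_kymo())
        v2 = rft.wave_speed(wave_kymo(wavelength_fraction=0.5))
        assert v2 == pytest.approx(0.5 * v1, rel=0.03)

    def test_white_noise_raises(self):
        rng = np.random.default_rng(1)
        k = wb.CurvatureKymograph(values=rng.normal(size=(150, 100)), frame_rate=5.0)
        with pytest.raises(WaveSpeedError):
            rft.wave_speed(k)

    def test_sign_reverses_for_tailward_origin(self):
        k = wave_kymo()
        rev = wb.CurvatureKymograph(values=k.values[:, ::-1].copy(), frame_rate=5.0)
        assert rft.wave_speed(rev) == pytest.approx(-1.0, rel=0.03)


class TestAngleOfAttack:
    def test_straight_glide_is_zero(self):
        cl = wb.centerline_from_curvature(np.zeros(100), 1.0)
        assert rft.angle_of_attack([cl], np.array([1.0, 0.0])) == pytest.approx(0.0, abs=1e-9)

    def test_sinusoidal_posture_mean_abs_angle(self):
        # psi(s, t) = psi0 sin(.) -> mean |psi| = (2/pi) psi0, within 2%
        k = wave_kymo(curvature_amplitude=2.0, duration=5.0, frame_rate=20.0)
        cls = [wb.centerline_from_curvature(k.values[i], 1.0)
               for i in range(k.n_frames)]
        psi0 = 2.0 * 1.0 / (2 * np.pi)  # A * lambda / (2 pi), radians
        expected = np.degrees((2 / np.pi) * psi0)
        theta = rft.angle_of_attack(cls, np.array([1.0, 0.0]))
        assert theta == pytest.approx(expected, rel=0.02)

    def test_small_angle_linearity(self):
        thetas = []
        for a in (0.5, 1.0):
            k = wave_kymo(curvature_amplitude=a, duration=5.0, frame_rate=20.0)
            cls = [wb.centerline_from_curvature(k.values[i], 1.0)
                   for i in range(k.n_frames)]
            thetas.append(rft.angle_of_attack(cls, np.array([1.0, 0.0])))
        assert thetas[1] == pytest.approx(2 * thetas[0], rel=0.03)

    def test_zero_displacement_direction_raises(self):
        cl = wb.centerline_from_curvature(np.zeros(100), 1.0)
        with pytest.raises(DataError):
            rft.angle_of_attack([cl], np.zeros(2))


class TestEfficiencyCurve:
    def test_zero_angle_zero_efficiency(self):
        assert wb.rft_efficiency_smallangle(0.0, 1.6) == 0.0

    def test_isotropic_drag_zero_efficiency(self):
        assert wb.rft_efficiency_smallangle(30.0, 1.0) == 0.0

    def test_monotone_increasing_in_angle(self):
        eta = wb.rft_efficiency_smallangle(np.linspace(0, 60, 50), 1.6)
        assert np.all(np.diff(eta) > 0)

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ConfigurationError):
            wb.rft_efficiency_smallangle(95.0, 1.6)
        with pytest.raises(ConfigurationError):
            wb.rft_efficiency_smallangle(10.0, -1.0)


class TestForceBalanceOracle:
    def test_isotropic_drag_gives_no_propulsion(self):
        res = rft.rft_force_balance(1.0, curvature_amplitude=2.0,
                                    steps_per_period=200, n_points=101)
        assert abs(res.v_a) < 1e-6

    def test_reversing_wave_reverses_motion(self):
        fwd = rft.rft_force_balance(1.6, curvature_amplitude=2.0,
                                    wavelength_fraction=1.0,
                                    steps_per_period=200, n_points=101)
        rev = rft.rft_force_balance(1.6, curvature_amplitude=2.0,
                                    wavelength_fraction=1.0, frequency=-1.0,
                                    steps_per_period=200, n_points=101)
        assert rev.v_a == pytest.approx(fwd.v_a, rel=1e-3)
        assert np.dot(fwd.direction, rev.direction) < -0.99

    def test_efficiency_monotone_in_drag_ratio(self):
        effs = [rft.rft_force_balance(K, curvature_amplitude=2.0,
                                      steps_per_period=150, n_points=101).efficiency
                for K in (1.2, 1.4, 1.6, 1.8, 2.0)]
        assert np.all(np.diff(effs) > 0)

    @pytest.mark.parametrize("K", [1.2, 2.0])
    @pytest.mark.parametrize("amplitude", [1.76, 10.3])  # theta_a ~ 2.5 and ~15 deg
    def test_smallangle_formula_matches_oracle(self, K, amplitude):
        # many-wavelength prescription approximates the infinite-filament
        # limit of the closed form; agreement within 5% for theta_a <= 15 deg
        res = rft.rft_force_balance(K, curvature_amplitude=amplitude,
                                    wavelength_fraction=0.25,
                                    steps_per_period=200, n_points=151)
        assert res.theta_a <= 15.5
        pred = wb.rft_efficiency_smallangle(res.theta_a, K)
        assert pred == pytest.approx(res.efficiency, rel=0.05)


class TestDragRatioFit:
    def test_noise_free_closure_to_four_digits(self):
        df = wb.make_rft_bouts(1.3, 50, (5, 45), 0.0, seed=0)
        res = wb.fit_drag_ratio(df, n_boot=0)
        assert res.K == pytest.approx(1.3, abs=5e-5)

    def test_all_zero_efficiencies_flagged_at_boundary(self):
        res = wb.DragRatioModel(np.zeros(20), np.linspace(5, 45, 20)).fit(n_boot=0)
        assert res.at_boundary

    def test_noisy_recovery_rate(self):
        hits = 0
        for seed in range(20):
            df = wb.make_rft_bouts(1.6, 100, (5, 45), 0.05, seed=seed)
            res = wb.fit_drag_ratio(df, n_boot=0)
            hits += abs(res.K - 1.6) <= 0.1
        assert hits >= 18

    def test_asymptotic_bias_below_one_percent(self):
        df = wb.make_rft_bouts(1.6, 1000, (5, 45), 0.0, seed=1)
        res = wb.fit_drag_ratio(df, n_boot=0)
        assert abs(res.K - 1.6) / 1.6 < 0.01

    def test_bootstrap_se_and_summary(self):
        df = wb.make_rft_bouts(1.6, 100, (5, 45), 0.05, seed=0)
        res = wb.fit_drag_ratio(df, n_boot=100, seed=0)
        assert res.bse is not None and 0 < res.bse < 0.5
        lo, hi = res.conf_int()
        assert lo < res.K < hi
        assert "C_perp/C_par" in res.summary()

    def test_too_few_bouts_raises(self):
        with pytest.raises(DataError):
            wb.DragRatioModel(np.array([0.1, 0.2]), np.array([10.0, 20.0]))


class TestBinning:
    def test_two_bouts_mean_and_sem(self):
        df = pd.DataFrame({"theta_a_deg": [12.0, 13.0], "v_a": [0.1, 0.3],
                           "v_w": [1.0, 1.0]})
        out = rft.bin_by_angle(df, bin_width=5.0)
        assert len(out) == 1
        assert out.loc[0, "va_mean"] == pytest.approx(0.2)
        assert out.loc[0, "va_sem"] == pytest.approx(0.1)

    def test_single_bout_sem_is_missing(self):
        df = pd.DataFrame({"theta_a_deg": [12.0], "v_a": [0.1], "v_w": [1.0]})
        out = rft.bin_by_angle(df)
        assert np.isnan(out.loc[0, "va_sem"]) and out.loc[0, "n"] == 1

    def test_actual_speed_has_interior_maximum(self):
        # V_w decreasing with angle, efficiency rising per RFT:
        # V_a = eta * V_w peaks at an intermediate angle of attack
        theta = np.linspace(5, 60, 200)
        v_w = 1.4 - 0.018 * theta
        v_a = wb.rft_efficiency_smallangle(theta, 1.6) * v_w
        df = pd.DataFrame({"theta_a_deg": theta, "v_a": v_a, "v_w": v_w})
        out = rft.bin_by_angle(df, bin_width=5.0)
        i = out["va_mean"].idxmax()
        assert 0 < i < len(out) - 1


class TestEpochChange:
    def test_identical_epochs_zero_change(self):
        df = pd.DataFrame({"v_a": [0.2, 0.3], "efficiency": [0.1, 0.2]})
        assert rft.epoch_fractional_change(df, df, "v_a") == 0.0

    def test_halved_speed_gives_minus_half(self):
        pre = pd.DataFrame({"v_a": [0.2, 0.4]})
        dur = pd.DataFrame({"v_a": [0.1, 0.2]})
        assert rft.epoch_fractional_change(pre, dur, "v_a") == pytest.approx(-0.5)

    def test_zero_pre_mean_raises(self):
        pre = pd.DataFrame({"v_a": [0.0]})
        dur = pd.DataFrame({"v_a": [0.1]})
        with pytest.raises(DataError):
            rft.epoch_fractional_change(pre, dur, "v_a")

    def test_amplitude_reduction_reduces_speed_across_trials(self):
        # "stimulation" halves wave amplitude -> negative median V_a change
        changes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            theta_pre = rng.uniform(30, 45, 5)
            theta_dur = theta_pre / 2  # smaller bending -> smaller angle
            v_w = 1.0
            pre = pd.DataFrame({"v_a": wb.rft_efficiency_smallangle(theta_pre, 1.6) * v_w})
            dur = pd.DataFrame({"v_a": wb.rft_efficiency_smallangle(theta_dur, 1.6) * v_w})
            changes.append(rft.epoch_fractional_change(pre, dur, "v_a"))
        assert np.median(changes) < 0


class TestBoutKinematics:
    def test_efficiency_is_va_over_vw_and_bounded(self):
        # kinematic drift at 0.3 mm/s with a 1 mm/s wave
        p = wb.WaveParams(curvature_amplitude=3.0, duration=15.0)
        k = wb.make_curvature_wave(p)
        t = np.arange(k.n_frames) / k.frame_rate
        track = np.stack([0.3 * t, np.zeros_like(t)], axis=1)
        b = rft.segment_bouts(k, track, min_duration=10.0)[0]
        rft.bout_kinematics(b, k, track)
        assert b.efficiency == pytest.approx(b.v_a / b.v_w, rel=1e-12)
        assert 0 <= b.efficiency <= 1
        assert b.head_amplitude is not None and b.head_amplitude > 0

    def test_frame_rate_invariance(self):
        # same trajectory sampled at 5 and 10 Hz: V_w and V_a agree within 3%
        out = {}
        for fr in (5.0, 10.0):
            p = wb.WaveParams(curvature_amplitude=3.0, duration=20.0, frame_rate=fr)
            k = wb.make_curvature_wave(p)
            t = np.arange(k.n_frames) / fr
            track = np.stack([0.25 * t, np.zeros_like(t)], axis=1)
            b = rft.segment_bouts(k, track, min_duration=10.0)[0]
            rft.bout_kinematics(b, k, track)
            out[fr] = (b.v_a, b.v_w)
        assert out[5.0][0] == pytest.approx(out[10.0][0], rel=0.03)
        assert out[5.0][1] == pytest.approx(out[10.0][1], rel=0.03)
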