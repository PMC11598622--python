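"""Amplitude-extraction chain: filter responses, whitening, gains."""

import numpy as np
import pytest

from emgtorque.preprocessing import (
    _cheby_lowpass,
    compute_gains,
    condition_torque,
    extract_amplitude,
    highpass_emg,
    notch_bank,
    whiten_first_difference,
)
from emgtorque.protocols import Trial


def _steady_amplitude(y, fs, skip_s=1.0):
    tail = y[int(skip_s * fs):]
    return (tail.max() - tail.min()) / 2


class TestHighpass:
    def test_dc_rejection(self):
        fs = 2048.0
        y = highpass_emg(np.ones(int(3 * fs)), fs)
        assert np.max(np.abs(y[int(fs):])) < 1e-3

    def test_zero_input(self):
        assert not np.any(highpass_emg(np.zeros(1000), 2048.0))

    def test_passband_100hz_within_one_percent(self):
        fs = 2048.0
        t = np.arange(int(4 * fs)) / fs
        y = highpass_emg(np.sin(2 * np.pi * 100 * t), fs)
        assert abs(_steady_amplitude(y, fs, 2.0) - 1.0) < 0.01

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            highpass_emg(np.zeros(100), 25.0)


class TestNotchBank:
    def test_60hz_attenuated_20db(self):
        fs = 2048.0
        t = np.arange(int(6 * fs)) / fs
        y = notch_bank(np.sin(2 * np.pi * 60 * t), fs)
        assert _steady_amplitude(y, fs, 4.0) < 10 ** (-20 / 20)

    def test_45hz_untouched(self):
        fs = 2048.0
        t = np.arange(int(6 * fs)) / fs
        y = notch_bank(np.sin(2 * np.pi * 45 * t), fs)
        att_db = -20 * np.log10(_steady_amplitude(y, fs, 4.0))
        assert att_db < 0.5

    def test_zero_input(self):
        assert not np.any(notch_bank(np.zeros(4096), 2048.0))


class TestWhitening:
    def test_constant_trace(self):
        y = whiten_first_difference(np.full(10, 3.3))
        assert y[0] == pytest.approx(3.3)
        assert not np.any(y[1:])

    def test_unit_ramp(self):
        y = whiten_first_difference(np.arange(6.0))
        assert np.array_equal(y, [0, 1, 1, 1, 1, 1])

    def test_white_noise_variance_doubles(self):
        x = np.random.default_rng(0).standard_normal(200_000)
        y = whiten_first_difference(x)
        assert y.var() / x.var() == pytest.approx(2.0, rel=0.02)


class TestExtractAmplitude:
    def test_frame_count_4096(self):
        env = extract_amplitude(np.random.default_rng(1).standard_normal((40960, 2)),
                                4096.0)
        assert env.n_frames == 409 and env.decimation_factor == 100

    def test_frame_rate_exact_both_rates(self):
        for fs, d in ((4096.0, 100), (2048.0, 50)):
            env = extract_amplitude(np.zeros((int(fs), 1)), fs)
            assert env.decimation_factor == d
            assert env.frame_rate == 40.96

    def test_zero_input_zero_envelope(self):
        env = extract_amplitude(np.zeros((4096, 3)), 2048.0)
        assert not np.any(env.values)

    def test_nonnegative(self):
        x = np.random.default_rng(2).standard_normal((8192, 2))
        assert np.all(extract_amplitude(x, 2048.0).values >= 0)

    def test_scale_equivariance(self):
        x = np.random.default_rng(3).standard_normal((8192, 2))
        a = extract_amplitude(x, 2048.0).values
        b = extract_amplitude(3.7 * x, 2048.0).values
        assert np.allclose(b, 3.7 * a, rtol=1e-10)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            extract_amplitude(np.zeros((1000, 1)), 1000.0)

    def test_chain_identity(self):
        # composite equals sequential application of the published stages
        fs = 2048.0
        x = np.random.default_rng(4).standard_normal((4096, 2))
        y = highpass_emg(x, fs)
        y = notch_bank(y, fs)
        y = whiten_first_difference(y)
        y = _cheby_lowpass(y, fs, 600.0)
        y = np.abs(y)
        y = _cheby_lowpass(y, fs, 16.0)
        y = np.maximum(y[49::50], 0.0)
        assert np.allclose(extract_amplitude(x, fs).values, y)

    def test_modulation_recovery_self_calibrated(self):
        # constant modulation s = 0.3 recovers 0.3 x (chain gain at s = 1)
        from scipy import signal as sg
        fs = 2048.0
        rng = np.random.default_rng(5)
        sos = sg.butter(4, [15, 600], btype="bandpass", fs=fs, output="sos")
        w = sg.sosfilt(sos, rng.standard_normal(int(30 * fs)))
        w /= w.std()
        ref = np.median(extract_amplitude(1.0 * w, fs).values[41:])
        est = np.median(extract_amplitude(0.3 * w, fs).values[41:])
        assert abs(est / (0.3 * ref) - 1.0) < 0.20


class TestConditionTorque:
    def test_constant_passthrough(self):
        y = condition_torque(np.full(8192, 25.0), 2048.0)
        assert np.allclose(y[82:], 25.0, rtol=0.01)

    def test_frame_count_matches_envelope(self):
        n = 8191
        env = extract_amplitude(np.zeros((n, 1)), 2048.0)
        y = condition_torque(np.zeros(n), 2048.0)
        assert y.shape[0] == env.n_frames

    def test_passband_half_hertz_within_two_percent(self):
        fs = 2048.0
        t = np.arange(int(10 * fs)) / fs
        y = condition_torque(np.sin(2 * np.pi * 0.5 * t), fs)
        tail = y[int(4 * 40.96):]
        assert abs((tail.max() - tail.min()) / 2 - 1.0) < 0.02

    def test_gain_scales_to_pct_mvt(self):
        y = condition_torque(np.full(4096, 40.0), 2048.0, torque_gain=1 / 80.0)
        assert y[-1] == pytest.approx(50.0, rel=0.01)


def _trial(emg, fs=2048.0, kind="calibration_pos"):
    n = emg.shape[0]
    return Trial(emg=emg, torque=np.zeros(n), fs=fs, dof="d",
                 kind=kind, subject_id="s", trial_id=0)


class TestGains:
    def test_emg_gain_is_reciprocal_of_larger_rms(self):
        n = 10240
        pos = _trial(np.full((n, 1), 0.2))
        neg = _trial(np.full((n, 1), 0.4), kind="calibration_neg")
        g = compute_gains(pos, neg, 100.0, 90.0)
        assert g.emg_gain[0] == pytest.approx(2.5)

    def test_normalized_larger_direction_rms_is_one(self):
        rng = np.random.default_rng(6)
        pos = _trial(0.13 * rng.standard_normal((10240, 2)))
        neg = _trial(0.29 * rng.standard_normal((10240, 2)), kind="calibration_neg")
        g = compute_gains(pos, neg, 100.0, 100.0)
        scaled = neg.emg * g.emg_gain[None, :]
        assert np.allclose(np.sqrt(np.mean(scaled**2, axis=0)), 1.0)

    def test_torque_gain_uses_larger_mvt(self):
        pos = _trial(np.full((10240, 1), 0.2))
        neg = _trial(np.full((10240, 1), 0.2), kind="calibration_neg")
        assert compute_gains(pos, neg, 80.0, 100.0).torque_gain == pytest.approx(0.01)

    def test_degenerate_channel_rejected(self):
        pos = _trial(np.zeros((10240, 1)))
        neg = _trial(np.zeros((10240, 1)), kind="calibration_neg")
        with pytest.raises(ValueError):
            compute_gains(pos, neg, 100.0, 100.0)
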