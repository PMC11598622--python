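"""Synthetic-data generator: spectra, ranges, modulation identity, counts."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import signal

from emgtorque.protocols import SOURCE, TARGET, DomainProtocol, SubjectGroundTruth
from emgtorque.synth import (
    generate_bandlimited_target,
    sample_ground_truth,
    synthesize_domain,
    synthesize_identification_data,
    synthesize_trial,
)


class TestBandlimitedTarget:
    def test_length_and_range(self):
        u = generate_bandlimited_target(1.0, 100.0, 1.0, 50.0, seed=7)
        assert u.shape == (100,)
        assert np.all(np.abs(u) <= 50.0 + 1e-9)

    def test_zero_range_gives_zero_trace(self):
        assert not np.any(generate_bandlimited_target(2.0, 100.0, 1.0, 0.0, seed=3))

    def test_fills_range(self):
        u = generate_bandlimited_target(40.0, 2048.0, 0.75, 30.0, seed=1)
        assert np.isclose(u.max(), 30.0) and np.isclose(u.min(), -30.0)

    def test_spectral_concentration(self):
        # >= 99% of periodogram power below 1.5x the bandlimit
        u = generate_bandlimited_target(40.0, 2048.0, 0.75, 30.0, seed=1)
        f, p = signal.periodogram(u, fs=2048.0)
        assert p[f <= 1.5 * 0.75].sum() / p.sum() >= 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_power_above_twice_cutoff_below_one_percent(self, seed):
        u = generate_bandlimited_target(20.0, 204.8, 0.75, 30.0, seed=seed)
        f, p = signal.periodogram(u, fs=204.8)
        assert p[f > 2 * 0.75].sum() / p.sum() < 0.01

    @pytest.mark.parametrize("bad", [
        dict(duration=0.0), dict(fs=-1.0), dict(cutoff=0.0), dict(range_pct=-5.0),
    ])
    def test_invalid_arguments_rejected(self, bad):
        kw = dict(duration=1.0, fs=100.0, cutoff=1.0, range_pct=10.0, seed=0)
        kw.update(bad)
        with pytest.raises(ValueError):
            generate_bandlimited_target(
                kw["duration"], kw["fs"], kw["cutoff"], kw["range_pct"], kw["seed"]
            )


class TestSynthesizeTrial:
    def test_determinism_bit_identical(self, tiny_protocol, desk_truth):
        truth = sample_ground_truth(tiny_protocol, 5)
        a = synthesize_trial(tiny_protocol, truth, "d1", "dynamic", 11)
        b = synthesize_trial(tiny_protocol, truth, "d1", "dynamic", 11)
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.torque, b.torque)

    def test_unknown_dof_or_kind_rejected(self, tiny_protocol):
        truth = sample_ground_truth(tiny_protocol, 5)
        with pytest.raises(ValueError):
            synthesize_trial(tiny_protocol, truth, "nope", "dynamic", 0)
        with pytest.raises(ValueError):
            synthesize_trial(tiny_protocol, truth, "d1", "warmup", 0)

    def test_modulation_identity_calibration(self, tiny_protocol):
        # with interference and sensor noise off, per-channel EMG RMS over a
        # long constant contraction matches the latent amplitude (unit
        # variance carrier)
        truth = sample_ground_truth(
            tiny_protocol, 5, line_amplitude=0.0, sensor_noise_sd=0.0
        )
        t = synthesize_trial(tiny_protocol, truth, "d1", "calibration_pos", 3,
                             duration=60.0)
        rms = np.sqrt(np.mean(t.emg**2, axis=0))
        s = t.latent_amplitude.mean(axis=0)
        assert np.all(np.abs(rms / s - 1.0) < 0.03)

    def test_degenerate_linear_forward_model(self, tiny_protocol):
        # delta kernels, no saturation/noise: torque frames are an
        # instantaneous linear function of the rectified drive
        truth = sample_ground_truth(
            tiny_protocol, 5, saturation_coeff=0.0, noise_sd=0.0,
            line_amplitude=0.0, sensor_noise_sd=0.0,
        )
        nc = tiny_protocol.n_channels
        delta = np.zeros((nc, 1, 1))
        delta[:, 0, 0] = [1.0, -1.0]
        truth = SubjectGroundTruth(
            gain_pos=truth.gain_pos, gain_neg=truth.gain_neg,
            baseline_amplitude=truth.baseline_amplitude, kernels=delta,
            saturation_coeff=0.0, noise_sd=0.0,
            line_amplitude=0.0, sensor_noise_sd=0.0,
        )
        t = synthesize_trial(tiny_protocol, truth, "d1", "dynamic", 3)
        D = tiny_protocol.decimation_factor
        s = t.latent_amplitude
        # kernel sums are (1, -1) so the resting offset cancels exactly
        expected = 100.0 * (s[:, 0] - s[:, 1])
        torque_frames = t.torque[D - 1 :: D]
        assert np.allclose(torque_frames, expected, atol=1e-9)

    def test_latent_drive_within_range(self, tiny_protocol):
        truth = sample_ground_truth(tiny_protocol, 5)
        t = synthesize_trial(tiny_protocol, truth, "d1", "dynamic", 3)
        assert np.max(np.abs(t.latent_drive)) <= tiny_protocol.range_for("d1") + 1e-9

    def test_calibration_and_mvt_levels(self, tiny_protocol):
        truth = sample_ground_truth(tiny_protocol, 5)
        cal = synthesize_trial(tiny_protocol, truth, "d1", "calibration_pos", 3)
        mvt = synthesize_trial(tiny_protocol, truth, "d1", "mvt_neg", 3)
        assert np.all(cal.latent_drive == 50.0)
        assert np.all(mvt.latent_drive == -100.0)


class TestSynthesizeDomain:
    def test_counts_per_subject(self, tiny_protocol):
        ds = synthesize_domain(tiny_protocol, 2, 1)
        assert len(ds.subjects) == 2
        subj = ds.subjects["s000"]
        assert len(subj.get("d1", "dynamic")) == 4
        for kind in ("calibration_pos", "calibration_neg", "mvt_pos", "mvt_neg"):
            assert len(subj.get("d1", kind)) == 1

    def test_source_protocol_structure(self):
        # structural check on the elbow protocol (durations shortened only
        # to keep synthesis fast; channels/rate/DoFs untouched)
        proto = replace(SOURCE, trial_duration=3.0, calibration_duration=3.0,
                        mvt_duration=3.0)
        ds = synthesize_domain(proto, 1, 2)
        t = ds.subjects["s000"].get("elbow_ef", "dynamic")[0]
        assert t.emg.shape[1] == 8 and t.fs == 4096.0

    def test_target_protocol_structure(self):
        proto = replace(TARGET, trial_duration=3.0, calibration_duration=3.0,
                        mvt_duration=3.0)
        ds = synthesize_domain(proto, 1, 2)
        subj = ds.subjects["s000"]
        assert len(proto.dofs) == 4
        for dof in proto.dofs:
            assert len(subj.get(dof, "dynamic")) == 4
            assert subj.get(dof, "dynamic")[0].emg.shape[1] == 16
            assert subj.get(dof, "dynamic")[0].fs == 2048.0

    def test_same_master_seed_identical(self, tiny_protocol):
        a = synthesize_domain(tiny_protocol, 2, 77)
        b = synthesize_domain(tiny_protocol, 2, 77)
        for sid in a.subjects:
            for ta, tb in zip(a.subjects[sid].trials, b.subjects[sid].trials):
                assert np.array_equal(ta.emg, tb.emg)
                assert np.array_equal(ta.torque, tb.torque)


class TestIdentificationData:
    def test_exact_linear_system(self):
        rng = np.random.default_rng(0)
        kernels = rng.standard_normal((3, 16))
        amps, torque = synthesize_identification_data(kernels, 200, seed=4)
        # direct convolution oracle
        expected = np.zeros(200)
        for c in range(3):
            expected += np.convolve(amps[:, c], kernels[c])[:200]
        assert np.allclose(torque, expected, atol=1e-12)
        assert np.all(amps >= 0)
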