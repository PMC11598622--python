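"""Synthetic sEMG + torque data with the structure the analysis assumes.

The generator emulates constant-posture force-tracking experiments: a
subject tracks a bandlimited uniform random torque target while multichannel
surface EMG and joint torque are recorded.  The forward model is

* latent drive ``u(t)`` — the torque target in %MVT (bandlimited uniform
  random process for dynamic trials, constant for calibration/MVT trials);
* per-channel latent amplitude ``s_c(t) = g+_c max(u,0)/100 +
  g-_c max(-u,0)/100 + s0`` — direction-specific activation gains model
  agonist/antagonist muscle groups, ``s0`` is the resting amplitude;
* raw EMG ``x_c(t) = s_c(t) w_c(t) + line interference + sensor noise``
  where ``w_c`` is unit-variance Gaussian noise bandlimited to 15--600 Hz
  (the analog front-end band), independent across channels;
* torque ``T = sat(sum_c h_c * s_c) + noise`` — per-channel impulse
  responses ``h_c`` on the 40.96 Hz frame grid (support <= 391 ms) model the
  electromechanical dynamics, followed by a soft tanh saturation and
  additive Gaussian noise, then resampling to the recording rate.

Torque units follow the MVT = 100 convention: a sustained maximal effort
produces a pre-saturation torque of 100, so %MVT normalisation against the
measured MVT trials can be exercised exactly as in the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .protocols import (
    FRAME_RATE,
    DomainProtocol,
    SubjectGroundTruth,
    Trial,
)

__all__ = [
    "generate_bandlimited_target",
    "sample_ground_truth",
    "synthesize_trial",
    "synthesize_identification_data",
    "synthesize_domain",
    "Dataset",
    "SubjectData",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_bandlimited_target(
    duration: float, fs: float, cutoff: float, range_pct: float, seed
) -> np.ndarray:
    """Bandlimited uniform random torque target.

    An i.i.d. uniform sequence drawn at 2.5x the bandlimit is sample-held
    to the recording rate, lowpass filtered with a zero-phase 4th-order
    Butterworth at ``cutoff``, and affinely rescaled so its minimum/maximum
    hit ``-range_pct``/``+range_pct`` (%MVT).  Drawing the innovations at
    the bandlimit's own rate (rather than at ``fs``) keeps the marginal
    distribution close to uniform, so every trial exercises both torque
    directions across the full range — the property the tracking protocol
    relies on.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    if range_pct < 0:
        raise ValueError("range must be nonnegative")
    n = int(round(duration * fs))
    rng = _rng(seed)
    innovation_rate = 2.5 * cutoff
    m = max(int(np.ceil(duration * innovation_rate)) + 1, 4)
    levels = rng.uniform(-1.0, 1.0, size=m)
    if range_pct == 0:
        return np.zeros(n)
    hold_idx = np.minimum((np.arange(n) / fs * innovation_rate).astype(int), m - 1)
    white = levels[hold_idx]
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    lo, hi = x.min(), x.max()
    if hi - lo < np.finfo(float).tiny:
        return np.zeros(n)
    mid = 0.5 * (hi + lo)
    return (x - mid) * (2.0 * range_pct / (hi - lo))


def sample_ground_truth(
    protocol: DomainProtocol,
    seed,
    *,
    saturation_coeff: float = 2.5,
    noise_sd: float = 1.0,
    line_amplitude: float = 0.05,
    sensor_noise_sd: float = 0.02,
    n_taps: int = 16,
) -> SubjectGroundTruth:
    """Draw one subject's latent sEMG -> torque map.

    Channels alternate preferred direction; the agonist gain is an order of
    magnitude larger than the antagonist gain.  Impulse responses are
    gamma-shaped (``t exp(-t/tau)``, tau ~ 30--80 ms), signed by the
    channel's preferred direction, and scaled per DoF so that a sustained
    +100 %MVT drive yields a pre-saturation torque of 100.
    """
    rng = _rng(seed)
    nc, nd = protocol.n_channels, protocol.n_dofs
    gain_pos = np.empty((nc, nd))
    gain_neg = np.empty((nc, nd))
    kernels = np.zeros((nc, nd, n_taps))
    t = (np.arange(n_taps) + 1.0) / FRAME_RATE  # s, causal lags
    for d in range(nd):
        # which channels favour the positive direction for this DoF
        pref_pos = (np.arange(nc) + d) % 2 == 0
        strong = rng.uniform(0.7, 1.3, size=nc)
        weak = rng.uniform(0.03, 0.12, size=nc)
        gain_pos[:, d] = np.where(pref_pos, strong, weak)
        gain_neg[:, d] = np.where(pref_pos, weak, strong)
        tau = rng.uniform(0.030, 0.080, size=nc)
        for c in range(nc):
            h = t * np.exp(-t / tau[c])
            h /= h.sum()
            kernels[c, d] = np.where(pref_pos[c], 1.0, -1.0) * h
        # calibrate: constant u = +100 -> pre-saturation torque 100
        steady = sum(kernels[c, d].sum() * gain_pos[c, d] for c in range(nc))
        kernels[:, d] *= 100.0 / (steady * 100.0)
    return SubjectGroundTruth(
        gain_pos=gain_pos,
        gain_neg=gain_neg,
        baseline_amplitude=float(rng.uniform(0.02, 0.05)),
        kernels=kernels,
        saturation_coeff=saturation_coeff,
        noise_sd=noise_sd,
        line_amplitude=line_amplitude,
        sensor_noise_sd=sensor_noise_sd,
    )


def _soft_saturation(x: np.ndarray, k: float) -> np.ndarray:
    """Odd tanh-style compression with unit slope at 0; identity for k = 0."""
    if k == 0:
        return x
    return (100.0 / k) * np.tanh(k * x / 100.0)


def _bandlimited_carrier(rng, n, fs, nc):
    """Unit-variance Gaussian noise bandlimited to 15--600 Hz, per channel."""
    hi = min(600.0, 0.45 * fs)
    sos = signal.butter(4, [15.0, hi], btype="bandpass", fs=fs, output="sos")
    w = signal.sosfilt(sos, rng.standard_normal((n, nc)), axis=0)
    w /= w.std(axis=0, keepdims=True)
    return w


def synthesize_trial(
    protocol: DomainProtocol,
    truth: SubjectGroundTruth,
    dof: str,
    kind: str,
    seed,
    *,
    subject_id: str = "s00",
    trial_id: int = 0,
    duration: float | None = None,
) -> Trial:
    """Synthesize one trial under ``protocol`` for a subject with ``truth``.

    Dynamic trials track a bandlimited uniform target; calibration trials
    hold +/-50 %MVT and MVT trials +/-100 %MVT.  The returned
    :class:`~emgtorque.protocols.Trial` carries the latent per-channel
    amplitudes (40.96 Hz grid) and latent drive for parameter-recovery
    tests.
    """
    if dof not in protocol.dofs:
        raise ValueError(f"DoF {dof!r} not in protocol {protocol.name!r}")
    rng = _rng(seed)
    d_idx = protocol.dofs.index(dof)
    D = protocol.decimation_factor
    fs = protocol.fs

    if kind == "dynamic":
        dur = duration if duration is not None else protocol.trial_duration
        u = generate_bandlimited_target(
            dur, fs, protocol.target_bandlimit, protocol.range_for(dof), rng
        )
    elif kind in ("calibration_pos", "calibration_neg"):
        dur = duration if duration is not None else protocol.calibration_duration
        level = 50.0 if kind.endswith("pos") else -50.0
        u = np.full(int(round(dur * fs)), level)
    elif kind in ("mvt_pos", "mvt_neg"):
        dur = duration if duration is not None else protocol.mvt_duration
        level = 100.0 if kind.endswith("pos") else -100.0
        u = np.full(int(round(dur * fs)), level)
    else:
        raise ValueError(f"unknown trial kind {kind!r}")

    n = u.shape[0]
    nc = protocol.n_channels
    gp = truth.gain_pos[:, d_idx]
    gn = truth.gain_neg[:, d_idx]
    s0 = truth.baseline_amplitude
    # latent amplitude at the raw rate, then on the frame grid
    s_raw = (
        gp[None, :] * np.maximum(u, 0.0)[:, None]
        + gn[None, :] * np.maximum(-u, 0.0)[:, None]
    ) / 100.0 + s0
    frame_idx = np.arange(D - 1, n, D)  # keep-every-Dth convention
    s_frames = s_raw[frame_idx]

    # raw EMG: amplitude-modulated carrier + power line + sensor noise
    w = _bandlimited_carrier(rng, n, fs, nc)
    emg = s_raw * w
    if truth.line_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=nc)
        tt = np.arange(n) / fs
        emg = emg + truth.line_amplitude * np.sin(
            2 * np.pi * protocol.line_freq * tt[:, None] + phases[None, :]
        )
    if truth.sensor_noise_sd > 0:
        emg = emg + truth.sensor_noise_sd * rng.standard_normal((n, nc))

    # torque on the frame grid: per-channel convolution, saturation, noise
    h = truth.kernels[:, d_idx, :]  # [nc, n_taps]
    nf = s_frames.shape[0]
    torque_f = np.zeros(nf)
    for c in range(nc):
        torque_f += signal.lfilter(h[c], [1.0], s_frames[:, c] * 100.0)
    torque_f -= 100.0 * s0 * h.sum()  # remove resting offset
    torque_f = _soft_saturation(torque_f, truth.saturation_coeff)
    if truth.noise_sd > 0:
        torque_f = torque_f + truth.noise_sd * rng.standard_normal(nf)
    torque = np.interp(np.arange(n), frame_idx, torque_f)

    return Trial(
        emg=emg,
        torque=torque,
        fs=fs,
        dof=dof,
        kind=kind,
        subject_id=subject_id,
        trial_id=trial_id,
        latent_amplitude=s_frames,
        latent_drive=u,
    )


def synthesize_identification_data(
    kernels: np.ndarray,
    n_frames: int,
    seed,
    *,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
):
    """Broadband independent excitation for FIR parameter recovery.

    Under the tracking protocols every channel's amplitude is driven by the
    same scalar target, so per-channel kernels are not identifiable from
    protocol trials.  This helper instead draws independent nonnegative
    white amplitudes per channel and passes them through the linear kernel
    bank, giving a well-conditioned identification problem with known
    ground truth.

    Parameters
    ----------
    kernels : [n_channels, n_taps] per-channel impulse responses (40.96 Hz).
    n_frames : number of amplitude frames to generate.
    seed : RNG seed.
    noise_sd : additive torque noise SD (default 0 — exact linear system).
    baseline : constant added to the amplitudes.

    Returns
    -------
    (amplitudes [n_frames, n_channels], torque [n_frames])
    """
    rng = _rng(seed)
    nc, _ = kernels.shape
    amps = rng.uniform(0.0, 1.0, size=(n_frames, nc)) + baseline
    torque = np.zeros(n_frames)
    for c in range(nc):
        torque += signal.lfilter(kernels[c], [1.0], amps[:, c])
    if noise_sd > 0:
        torque = torque + noise_sd * rng.standard_normal(n_frames)
    return amps, torque


@dataclass
class SubjectData:
    """All trials for one synthetic subject, with the generating ground truth."""

    subject_id: str
    truth: SubjectGroundTruth
    trials: list[Trial] = field(default_factory=list)

    def get(self, dof: str, kind: str) -> list[Trial]:
        out = [t for t in self.trials if t.dof == dof and t.kind == kind]
        return sorted(out, key=lambda t: t.trial_id)


@dataclass
class Dataset:
    """A full synthetic domain: subjects x DoFs x trials + calibration/MVT."""

    protocol: DomainProtocol
    subjects: dict[str, SubjectData] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)


def synthesize_domain(
    protocol: DomainProtocol,
    n_subjects: int,
    master_seed: int,
    **truth_kwargs,
) -> Dataset:
    """Generate a complete domain dataset.

    Per-subject seeds are spawned deterministically from ``master_seed``;
    the same master seed always yields byte-identical datasets.  Each
    subject gets ``trials_per_dof`` dynamic trials plus one calibration and
    one MVT trial per direction for every DoF.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ds = Dataset(protocol=protocol)
    root = np.random.SeedSequence(master_seed)
    for subj_seq in root.spawn(n_subjects):
        streams = subj_seq.spawn(2)
        sid = f"s{len(ds.subjects):03d}"
        truth = sample_ground_truth(
            protocol, np.random.default_rng(streams[0]), **truth_kwargs
        )
        trial_rng = np.random.default_rng(streams[1])
        subj = SubjectData(subject_id=sid, truth=truth)
        for dof in protocol.dofs:
            for k in range(protocol.trials_per_dof):
                subj.trials.append(
                    synthesize_trial(
                        protocol, truth, dof, "dynamic", trial_rng,
                        subject_id=sid, trial_id=k,
                    )
                )
            for kind in ("calibration_pos", "calibration_neg", "mvt_pos", "mvt_neg"):
                subj.trials.append(
                    synthesize_trial(
                        protocol, truth, dof, kind, trial_rng,
                        subject_id=sid, trial_id=0,
                    )
                )
        ds.subjects[sid] = subj
    return ds
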