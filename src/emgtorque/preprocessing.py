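"""sEMG amplitude extraction, torque conditioning and normalisation.

The amplitude of a surface EMG channel — its time-varying standard
deviation — is estimated by the classical filter chain:

1. 5th-order Butterworth highpass at 15 Hz (motion artifact removal);
2. cascade of 2nd-order IIR notches (-3 dB bandwidth <= 1.5 Hz) at the
   power-line fundamental and all harmonics below the 600 Hz lowpass;
3. first-difference whitening ``y[n] = x[n] - x[n-1]`` (variance reduction);
4. 9th-order Chebyshev Type I lowpass at 600 Hz (wideband noise removal);
5. full-wave rectification;
6. 9th-order Chebyshev Type I lowpass at 16 Hz (smoothing);
7. decimation to 40.96 Hz by keeping every D-th sample, D = fs/40.96.

All filtering is causal (forward-only): the intended application is
real-time myoelectric control, and start-up transients are handled by the
evaluation stage's 1 s edge omission.  Chebyshev passband ripple is 0.05 dB
(small enough for a flat passband; configurable).

Normalisation follows the calibration-contraction convention: each EMG
channel is scaled by the reciprocal of the larger of its two 50 %MVT
calibration RMS values (one per direction), and torque is scaled to %MVT
of the larger direction's maximum voluntary torque.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .protocols import FRAME_RATE, Trial

__all__ = [
    "AmplitudeEnvelope",
    "NormalizationGains",
    "highpass_emg",
    "notch_bank",
    "whiten_first_difference",
    "extract_amplitude",
    "condition_torque",
    "compute_gains",
    "measure_mvt",
    "filter_designs",
    "export_filter_designs",
]

CHEBY_RIPPLE_DB = 0.05


def _decimation_factor(fs: float) -> int:
    d = fs / FRAME_RATE
    if abs(d - round(d)) > 1e-9:
        raise ValueError(f"fs = {fs} Hz is not an integer multiple of {FRAME_RATE} Hz")
    return int(round(d))


@dataclass
class AmplitudeEnvelope:
    """Nonnegative per-channel sEMG amplitude on the 40.96 Hz frame grid."""

    values: np.ndarray  # [n_frames, n_channels]
    source_fs: float
    decimation_factor: int
    frame_rate: float = FRAME_RATE

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("amplitude envelope must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationGains:
    """Per-DoF normalisation: EMG channel gains and the torque %MVT gain."""

    emg_gain: np.ndarray  # [n_channels]
    torque_gain: float    # 1 / max(MVT+, MVT-)
    dof: str = ""

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.emg_gain)) and np.all(self.emg_gain > 0)):
            raise ValueError("EMG gains must be finite and positive")
        if not (np.isfinite(self.torque_gain) and self.torque_gain > 0):
            raise ValueError("torque gain must be finite and positive")


def highpass_emg(x: np.ndarray, fs: float, cutoff: float = 15.0) -> np.ndarray:
    """Causal 5th-order Butterworth highpass (default 15 Hz)."""
    if fs <= 2 * cutoff:
        raise ValueError(f"fs = {fs} Hz too low for a {cutoff} Hz highpass")
    sos = signal.butter(5, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfilt(sos, x, axis=0)


def notch_bank(
    x: np.ndarray,
    fs: float,
    f0: float = 60.0,
    bandwidth: float = 1.5,
    max_freq: float = 600.0,
) -> np.ndarray:
    """Cascade of 2nd-order notches at ``f0`` and harmonics below ``max_freq``.

    Each notch has a -3 dB bandwidth of ``bandwidth`` Hz.  Harmonics at or
    above the subsequent lowpass cutoff (or Nyquist) are skipped — the
    lowpass removes them anyway.
    """
    if f0 >= fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    y = x
    limit = min(max_freq, 0.999 * fs / 2)
    freq = f0
    while freq < limit:
        b, a = signal.iirnotch(freq, Q=freq / bandwidth, fs=fs)
        y = signal.lfilter(b, a, y, axis=0)
        freq += f0
    return y


def whiten_first_difference(x: np.ndarray) -> np.ndarray:
    """Exact first difference, ``y[0] = x[0]``; length preserved."""
    x = np.asarray(x)
    if x.shape[0] < 1:
        raise ValueError("need at least one sample")
    return np.diff(x, axis=0, prepend=np.zeros((1,) + x.shape[1:]))


def _cheby_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Causal 9th-order Chebyshev Type I lowpass; skipped if cutoff >= Nyquist."""
    if cutoff >= fs / 2:
        return x
    sos = signal.cheby1(9, CHEBY_RIPPLE_DB, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfilt(sos, x, axis=0)


def extract_amplitude(
    emg: np.ndarray,
    fs: float,
    *,
    channel_gains: np.ndarray | None = None,
    line_freq: float = 60.0,
) -> AmplitudeEnvelope:
    """Run the full amplitude-extraction chain on raw sEMG.

    Parameters
    ----------
    emg : [n_samples, n_channels] raw sEMG (a 1-D trace is treated as one
        channel).
    fs : sampling rate; must be an integer multiple of 40.96 Hz.
    channel_gains : optional per-channel normalisation gains applied to the
        raw signal before filtering (the chain is positively homogeneous,
        so this is equivalent to scaling the envelope).
    line_freq : power-line fundamental for the notch bank.
    """
    D = _decimation_factor(fs)
    x = np.atleast_2d(np.asarray(emg, dtype=float))
    if x.shape[0] == 1 and np.asarray(emg).ndim == 1:
        x = x.T
    if channel_gains is not None:
        x = x * np.asarray(channel_gains)[None, :]
    y = highpass_emg(x, fs)
    y = notch_bank(y, fs, f0=line_freq)
    y = whiten_first_difference(y)
    y = _cheby_lowpass(y, fs, 600.0)
    y = np.abs(y)
    y = _cheby_lowpass(y, fs, 16.0)
    y = y[D - 1 :: D]  # floor(n/D) frames
    return AmplitudeEnvelope(
        values=np.maximum(y, 0.0), source_fs=fs, decimation_factor=D
    )


def condition_torque(
    torque: np.ndarray, fs: float, *, torque_gain: float | None = None
) -> np.ndarray:
    """Lowpass (16 Hz Chebyshev) and decimate torque to the 40.96 Hz grid.

    With ``torque_gain`` given, the output is scaled to %MVT
    (``torque * gain * 100``); otherwise units are preserved.
    """
    D = _decimation_factor(fs)
    y = _cheby_lowpass(np.asarray(torque, dtype=float), fs, 16.0)
    y = y[D - 1 :: D]
    if torque_gain is not None:
        y = y * (torque_gain * 100.0)
    return y


def _raw_rms(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=0))


def measure_mvt(trial: Trial, omit_s: float = 1.0) -> float:
    """Estimate MVT magnitude from an MVT trial: median |torque| over the
    interior of the conditioned trace (robust to edge transients/noise)."""
    t = condition_torque(trial.torque, trial.fs)
    k = int(round(omit_s * FRAME_RATE))
    interior = t[k : len(t) - k] if len(t) > 2 * k else t
    return float(np.median(np.abs(interior)))


def compute_gains(
    cal_pos: Trial,
    cal_neg: Trial,
    mvt_pos: float,
    mvt_neg: float,
    *,
    dof: str = "",
) -> NormalizationGains:
    """Normalisation gains for one DoF.

    ``emg_gain_c = 1 / max(RMS_c(cal+), RMS_c(cal-))`` with RMS computed on
    the raw calibration traces; ``torque_gain = 1 / max(MVT+, MVT-)``.
    """
    rms = np.maximum(_raw_rms(cal_pos.emg), _raw_rms(cal_neg.emg))
    if np.any(rms <= 0):
        raise ValueError("degenerate channel: zero calibration RMS")
    mvt = max(abs(mvt_pos), abs(mvt_neg))
    if mvt <= 0:
        raise ValueError("degenerate DoF: zero MVT")
    return NormalizationGains(emg_gain=1.0 / rms, torque_gain=1.0 / mvt, dof=dof)


def filter_designs(fs: float, line_freq: float = 60.0) -> dict[str, np.ndarray]:
    """Second-order-section coefficients of every filter in the chain."""
    designs = {
        "highpass_15hz": signal.butter(5, 15.0, "highpass", fs=fs, output="sos"),
    }
    limit = min(600.0, 0.999 * fs / 2)
    freq = line_freq
    while freq < limit:
        b, a = signal.iirnotch(freq, Q=freq / 1.5, fs=fs)
        designs[f"notch_{int(freq)}hz"] = signal.tf2sos(b, a)
        freq += line_freq
    designs["whiten_first_difference"] = signal.tf2sos([1.0, -1.0], [1.0])
    if 600.0 < fs / 2:
        designs["lowpass_600hz"] = signal.cheby1(
            9, CHEBY_RIPPLE_DB, 600.0, "low", fs=fs, output="sos"
        )
    designs["lowpass_16hz"] = signal.cheby1(
        9, CHEBY_RIPPLE_DB, 16.0, "low", fs=fs, output="sos"
    )
    return designs


def export_filter_designs(path, fs: float, line_freq: float = 60.0) -> None:
    """Write the chain's SOS coefficients to a CSV for inspection."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filter", "section", "b0", "b1", "b2", "a0", "a1", "a2"])
        for name, sos in filter_designs(fs, line_freq).items():
            for i, sec in enumerate(np.atleast_2d(sos)):
                w.writerow([name, i] + [f"{v:.12g}" for v in sec])
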