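"""Sliding-window segmentation into the three model-input layouts.

Windows are defined on the 40.96 Hz amplitude frame grid: a window length
in milliseconds maps to ``M = round(ms/1000 * 40.96)`` frames (the eight
standard lengths 98..781 ms map to 4, 8, ..., 32 frames) and the 25 ms
increment maps to 1 frame.  Raw-signal windows use the same grid scaled by
the decimation factor ``D = fs/40.96``, so a 391 ms window is 16 frames,
800 raw samples at 2048 Hz, or 1600 raw samples at 4096 Hz, and raw and
amplitude windows for the same trial cover identical time spans.

Each window's regression target is the conditioned torque at the window's
final frame (causal, zero-lag estimation).

Layouts:

* ``mlp_vector``   — channel-major concatenation, length ``n_channels * M``;
* ``lstm_sequence`` — ``[M timesteps, n_channels]`` sequences;
* ``raw_image``    — ``[M * D raw samples, n_channels]`` images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import FRAME_RATE
from .preprocessing import AmplitudeEnvelope

__all__ = [
    "WINDOW_LENGTHS_MS",
    "WindowSpec",
    "WindowSet",
    "segment",
    "make_mlp_input",
    "make_sequence_input",
    "make_image_input",
    "window_length_table",
]

WINDOW_LENGTHS_MS = (98, 195, 293, 391, 488, 586, 684, 781)
"""The eight standard sliding-window lengths (ms); 391 ms = 16 frames."""


@dataclass(frozen=True)
class WindowSpec:
    """Window length / increment, resolved on the 40.96 Hz frame grid."""

    window_ms: float
    increment_ms: float = 25.0

    @property
    def frames(self) -> int:
        m = int(round(self.window_ms / 1000.0 * FRAME_RATE))
        if m < 1:
            raise ValueError(f"window of {self.window_ms} ms is below one frame")
        return m

    @property
    def step_frames(self) -> int:
        s = int(round(self.increment_ms / 1000.0 * FRAME_RATE))
        return max(s, 1)

    def raw_samples(self, fs: float) -> int:
        """Window length in raw samples: frames x decimation factor."""
        return self.frames * _decim(fs)

    def raw_step(self, fs: float) -> int:
        return self.step_frames * _decim(fs)


def _decim(fs: float) -> int:
    d = fs / FRAME_RATE
    if abs(d - round(d)) > 1e-9:
        raise ValueError(f"fs = {fs} Hz is not an integer multiple of {FRAME_RATE} Hz")
    return int(round(d))


def segment(n: int, window: int, step: int) -> np.ndarray:
    """Start indices of overlapping windows: 0, step, 2*step, ...

    The count is ``floor((n - window)/step) + 1``; a series shorter than one
    window is rejected.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if n < window:
        raise ValueError(f"series of length {n} shorter than window {window}")
    count = (n - window) // step + 1
    return np.arange(count) * step


@dataclass
class WindowSet:
    """A segmented trial: inputs ``X``, end-aligned targets ``y``."""

    X: np.ndarray          # layout-dependent batch
    y: np.ndarray          # [n_windows] %MVT at each window's final frame
    starts: np.ndarray     # frame-grid start indices
    frames: int            # window length in frames (M)
    step_frames: int
    layout: str            # mlp_vector | lstm_sequence | raw_image

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def end_times(self) -> np.ndarray:
        """Time (s) of each window's final frame, for edge omission."""
        return (self.starts + self.frames - 1 + 1) / FRAME_RATE


def _frame_targets(starts: np.ndarray, m: int, torque_frames: np.ndarray) -> np.ndarray:
    idx = starts + m - 1
    return np.asarray(torque_frames)[idx]


def _env_values(envelope) -> np.ndarray:
    if isinstance(envelope, AmplitudeEnvelope):
        return envelope.values
    return np.asarray(envelope)


def make_mlp_input(envelope, spec: WindowSpec, torque_frames: np.ndarray) -> WindowSet:
    """Concatenated feature vectors: all M samples of channel 1, then
    channel 2, ... (channel-major order), length ``n_channels * M``."""
    v = _env_values(envelope)
    m, step = spec.frames, spec.step_frames
    starts = segment(v.shape[0], m, step)
    X = np.stack([v[s : s + m].T.ravel() for s in starts])
    return WindowSet(
        X=X, y=_frame_targets(starts, m, torque_frames), starts=starts,
        frames=m, step_frames=step, layout="mlp_vector",
    )


def make_sequence_input(envelope, spec: WindowSpec, torque_frames: np.ndarray) -> WindowSet:
    """Channel sequences: ``[n_windows, M timesteps, n_channels]``."""
    v = _env_values(envelope)
    m, step = spec.frames, spec.step_frames
    starts = segment(v.shape[0], m, step)
    X = np.stack([v[s : s + m] for s in starts])
    return WindowSet(
        X=X, y=_frame_targets(starts, m, torque_frames), starts=starts,
        frames=m, step_frames=step, layout="lstm_sequence",
    )


def make_image_input(
    raw_emg: np.ndarray, spec: WindowSpec, fs: float, torque_frames: np.ndarray
) -> WindowSet:
    """Raw sEMG images ``[n_windows, M*D raw samples, n_channels]``.

    Windows are placed on the same frame grid as the amplitude layouts, so
    the k-th image spans exactly the same time interval as the k-th
    amplitude window and shares its torque target.
    """
    d = _decim(fs)
    m, step = spec.frames, spec.step_frames
    n_frames = min(raw_emg.shape[0] // d, len(torque_frames))
    starts = segment(n_frames, m, step)
    m_raw, step_raw = m * d, step * d
    X = np.stack([raw_emg[s * d : s * d + m_raw] for s in starts])
    return WindowSet(
        X=X, y=_frame_targets(starts, m, torque_frames), starts=starts,
        frames=m, step_frames=step, layout="raw_image",
    )


def window_length_table(fs_list=(2048.0, 4096.0)):
    """Resolved window sizes for the eight standard lengths (documentation
    aid; returned as a list of dicts, one per length)."""
    rows = []
    for ms in WINDOW_LENGTHS_MS:
        spec = WindowSpec(ms)
        row = {"window_ms": ms, "frames_at_40.96Hz": spec.frames}
        for fs in fs_list:
            row[f"raw_samples_at_{int(fs)}Hz"] = spec.raw_samples(fs)
        rows.append(row)
    return rows
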