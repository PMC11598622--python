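"""Recording-protocol descriptions and core data containers.

Two constant-posture, force-varying tracking protocols are modelled:

* ``SOURCE`` — elbow extension--flexion: 8 bipolar channels sampled at
  4096 Hz, one degree of freedom (DoF), 30 s dynamic trials whose torque
  target is a 1 Hz bandlimited uniform random process spanning +/-50 %MVT.
* ``TARGET`` — hand--wrist: 16 bipolar channels at 2048 Hz, four DoFs
  (wrist extension--flexion, radial--ulnar, pronation--supination, hand
  open--close), 40 s dynamic trials with a 0.75 Hz bandlimited target
  spanning +/-30 %MVT for the wrist DoFs and +/-15 %MVT for open--close.

Both protocols also include, per DoF and direction, a 5 s 50 %MVT
calibration contraction (used for normalisation gains) and a maximum
voluntary torque (MVT) trial.  The common envelope frame rate after
decimation is 40.96 Hz, so the sampling rate must be an integer multiple
of it (4096 = 100 x 40.96, 2048 = 50 x 40.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRAME_RATE = 40.96
"""Envelope frame rate in Hz shared by both domains after decimation."""

TRIAL_KINDS = ("dynamic", "calibration_pos", "calibration_neg", "mvt_pos", "mvt_neg")


def _check_frame_divisor(fs: float) -> int:
    d = fs / FRAME_RATE
    if abs(d - round(d)) > 1e-9 or round(d) < 1:
        raise ValueError(
            f"sampling rate {fs} Hz is not an integer multiple of {FRAME_RATE} Hz"
        )
    return int(round(d))


@dataclass(frozen=True)
class DomainProtocol:
    """Static description of one recording protocol (one joint)."""

    name: str
    n_channels: int
    fs: float
    dofs: tuple[str, ...]
    trials_per_dof: int
    trial_duration: float            # s, dynamic trials
    target_bandlimit: float          # Hz
    target_range: tuple[float, ...]  # %MVT per DoF
    line_freq: float = 60.0
    calibration_duration: float = 5.0
    mvt_duration: float = 5.0

    def __post_init__(self) -> None:
        _check_frame_divisor(self.fs)
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels (agonist + antagonist)")
        if self.trial_duration <= 2.0:
            raise ValueError("trial_duration must exceed 2 s (edge omission)")
        if len(self.target_range) != len(self.dofs):
            raise ValueError("target_range must list one %MVT range per DoF")

    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    @property
    def decimation_factor(self) -> int:
        """Samples per 40.96 Hz envelope frame (100 at 4096 Hz, 50 at 2048 Hz)."""
        return _check_frame_divisor(self.fs)

    def range_for(self, dof: str) -> float:
        return self.target_range[self.dofs.index(dof)]


SOURCE = DomainProtocol(
    name="source",
    n_channels=8,
    fs=4096.0,
    dofs=("elbow_ef",),
    trials_per_dof=3,
    trial_duration=30.0,
    target_bandlimit=1.0,
    target_range=(50.0,),
)

TARGET = DomainProtocol(
    name="target",
    n_channels=16,
    fs=2048.0,
    dofs=("wrist_ef", "wrist_ru", "wrist_ps", "hand_oc"),
    trials_per_dof=4,
    trial_duration=40.0,
    target_bandlimit=0.75,
    target_range=(30.0, 30.0, 30.0, 15.0),
)


@dataclass
class SubjectGroundTruth:
    """Latent per-subject parameters of the synthetic sEMG -> torque map.

    ``gain_pos``/``gain_neg`` are per-(channel, DoF) activation gains for the
    positive/negative torque direction; each channel is predominantly agonist
    for one direction.  ``kernels`` are per-(channel, DoF) torque impulse
    responses sampled on the 40.96 Hz frame grid (finite support <= 16 taps,
    i.e. <= 391 ms).  ``saturation_coeff`` sets the strength of the soft
    (tanh) amplitude-to-torque nonlinearity; 0 switches it off.  ``noise_sd``
    is additive torque noise in %MVT.
    """

    gain_pos: np.ndarray         # [n_channels, n_dofs]
    gain_neg: np.ndarray         # [n_channels, n_dofs]
    baseline_amplitude: float    # resting sEMG amplitude, raw units
    kernels: np.ndarray          # [n_channels, n_dofs, n_taps] at 40.96 Hz
    saturation_coeff: float
    noise_sd: float              # %MVT
    line_amplitude: float = 0.05   # raw units, power-line interference
    sensor_noise_sd: float = 0.02  # raw units, wideband sensor noise

    def __post_init__(self) -> None:
        if np.any(self.gain_pos < 0) or np.any(self.gain_neg < 0):
            raise ValueError("channel gains must be nonnegative")
        if self.kernels.shape[-1] > 16:
            raise ValueError("torque kernels must have support <= 16 frames (391 ms)")


@dataclass
class Trial:
    """One synthetic recording: raw multichannel sEMG plus the torque trace."""

    emg: np.ndarray        # [n_samples, n_channels] raw units
    torque: np.ndarray     # [n_samples] raw units (MVT convention: MVT ~= 100)
    fs: float
    dof: str
    kind: str
    subject_id: str
    trial_id: int
    latent_amplitude: np.ndarray | None = None  # [n_frames, n_channels] at 40.96 Hz
    latent_drive: np.ndarray | None = None      # [n_samples] %MVT target

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.emg.shape[0] != self.torque.shape[0]:
            raise ValueError("emg and torque must have equal length")
        if not (np.all(np.isfinite(self.emg)) and np.all(np.isfinite(self.torque))):
            raise ValueError("trial contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def duration(self) -> float:
        return self.emg.shape[0] / self.fs
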