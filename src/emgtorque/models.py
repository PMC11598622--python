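"""EMG-amplitude-to-torque regressors.

Two families:

* :class:`FirTorque` — the linear baseline: a per-channel FIR filter bank
  (default order 15, i.e. 16 lag taps spanning 391 ms at 40.96 Hz) from
  amplitude to torque, fitted by regularised least squares via the
  Moore--Penrose pseudo-inverse with singular values below a tolerance
  (default 0.005, relative to the largest) truncated.

* :class:`DnnTorque` — the four windowed deep regressors:

  - ``mlp``   — concatenated-amplitude vector input; FC 128 (linear, the
    input transformation), FC 128 + ReLU, FC 64 + ReLU, scalar output;
  - ``cnn``   — raw sEMG image input; four 3x3 convolution blocks with
    64/128/128/64 filters, batch norm on blocks 1--3, ReLU and 2x2
    stride-2 average pooling per block, dropout 0.5, FC 128 + ReLU, output;
  - ``lstm``  — amplitude sequence input; time-distributed FC 128 (linear),
    LSTM with 100 hidden units, FC 64 + ReLU, output;
  - ``clstm`` — raw image input; the four convolution blocks, LSTM with
    500 hidden units over the time axis, dropout 0.5, FC 128 + ReLU, output.

  Training uses Adam (initial learning rate 0.001, dropped by a factor of
  0.2 every 10 epochs), mini-batches of 256 shuffled every epoch, Glorot
  initialisation and mean-squared-error loss.  The epoch budget (default
  30, three learning-rate plateaus) is a package choice.

Both model classes follow the model/results idiom: construct from data,
``fit()`` returns a results object carrying estimates, diagnostics and a
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import AmplitudeEnvelope
from .windowing import WindowSet

__all__ = [
    "FirTorque", "FirTorqueResults", "fit_fir", "predict_fir",
    "DnnSpec", "TrainConfig", "build_network", "train_network",
    "DnnTorque", "DnnTorqueResults", "cnn_shape_trace",
]


# --------------------------------------------------------------------------
# FIR linear baseline
# --------------------------------------------------------------------------

def _env_values(envelope) -> np.ndarray:
    if isinstance(envelope, AmplitudeEnvelope):
        return envelope.values
    v = np.asarray(envelope, dtype=float)
    return v[:, None] if v.ndim == 1 else v


def _lagged_design(values: np.ndarray, order: int) -> np.ndarray:
    """Rows t = order..n-1; columns channel-major [s_c[t], .., s_c[t-order]]."""
    n, c = values.shape
    cols = []
    for ch in range(c):
        for lag in range(order + 1):
            cols.append(values[order - lag : n - lag, ch])
    return np.stack(cols, axis=1)


class FirTorque:
    """Linear FIR model from lagged amplitudes to torque (no intercept).

    Parameters
    ----------
    envelope : amplitude frames ``[n_frames, n_channels]`` (or an
        :class:`~emgtorque.preprocessing.AmplitudeEnvelope`).
    torque : %MVT torque frames, same length.
    order : FIR order; ``order + 1`` lag taps per channel (memory span
        ``(order+1)/40.96`` s).
    sv_tolerance : singular-value truncation threshold.
    relative : interpret the tolerance relative to the largest singular
        value (default) or as an absolute cutoff.
    """

    def __init__(self, envelope, torque, order: int = 15,
                 sv_tolerance: float = 0.005, relative: bool = True):
        if isinstance(envelope, (list, tuple)):
            self.segments = [
                (_env_values(e), np.asarray(t, dtype=float))
                for e, t in zip(envelope, torque)
            ]
        else:
            self.segments = [(_env_values(envelope), np.asarray(torque, dtype=float))]
        for v, t in self.segments:
            if v.shape[0] != t.shape[0]:
                raise ValueError("envelope and torque must have equal frame counts")
            if v.shape[0] <= order:
                raise ValueError("training segment empty after lagging")
        self.values = self.segments[0][0]
        self.torque = self.segments[0][1]
        self.order = order
        self.sv_tolerance = sv_tolerance
        self.relative = relative
        n_params = self.values.shape[1] * (order + 1)
        n_rows = sum(v.shape[0] - order for v, _ in self.segments)
        if n_rows < n_params:
            warnings.warn(
                f"only {n_rows} training frames for {n_params} FIR coefficients; "
                "the truncated-SVD solution will be rank limited",
                stacklevel=2,
            )

    def fit(self) -> "FirTorqueResults":
        A = np.vstack([_lagged_design(v, self.order) for v, _ in self.segments])
        y = np.concatenate([t[self.order :] for _, t in self.segments])
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        cutoff = self.sv_tolerance * (s[0] if self.relative else 1.0)
        keep = s > cutoff
        inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        theta = Vt.T @ (inv_s * (U.T @ y))
        n_ch = self.values.shape[1]
        coeffs = theta.reshape(n_ch, self.order + 1)
        resid = y - A @ theta
        return FirTorqueResults(
            model=self,
            coefficients=coeffs,
            singular_values=s,
            rank=int(keep.sum()),
            resid_rmse=float(np.sqrt(np.mean(resid**2))),
        )


@dataclass
class FirTorqueResults:
    """Fitted FIR filter bank with truncation diagnostics."""

    model: FirTorque
    coefficients: np.ndarray  # [n_channels, order+1]
    singular_values: np.ndarray
    rank: int
    resid_rmse: float

    def predict(self, envelope) -> np.ndarray:
        """Torque estimate (%MVT) per frame; zero-padded start-up history."""
        from scipy.signal import lfilter

        v = _env_values(envelope)
        out = np.zeros(v.shape[0])
        for c in range(v.shape[1]):
            out += lfilter(self.coefficients[c], [1.0], v[:, c])
        return out

    @property
    def memory_span_s(self) -> float:
        return (self.model.order + 1) / 40.96

    def summary(self) -> str:
        m = self.model
        lines = [
            "FIR amplitude-to-torque model",
            f"  channels: {m.values.shape[1]}   order: {m.order} "
            f"({m.order + 1} taps, {self.memory_span_s * 1000:.1f} ms memory)",
            f"  sv tolerance: {m.sv_tolerance} ({'relative' if m.relative else 'absolute'})",
            f"  design rank kept: {self.rank}/{len(self.singular_values)}",
            f"  training residual RMSE: {self.resid_rmse:.3f} %MVT",
        ]
        return "\n".join(lines)


def fit_fir(envelope, torque, order: int = 15, sv_tolerance: float = 0.005,
            relative: bool = True) -> FirTorqueResults:
    """Functional wrapper: fit the FIR baseline (see :class:`FirTorque`)."""
    return FirTorque(envelope, torque, order, sv_tolerance, relative).fit()


def predict_fir(results: FirTorqueResults, envelope) -> np.ndarray:
    return results.predict(envelope)


# --------------------------------------------------------------------------
# DNN architectures
# --------------------------------------------------------------------------

ARCHS = ("mlp", "cnn", "lstm", "clstm")

MLP_FC = (128, 128, 64)
CNN_FILTERS = (64, 128, 128, 64)
LSTM_FC_IN = 128
LSTM_UNITS = 100
LSTM_FC_OUT = 64
CLSTM_UNITS = 500
CNN_FC = 128
DROPOUT_RATE = 0.5


@dataclass(frozen=True)
class DnnSpec:
    """Architecture tag plus input shape.

    ``input_shape`` is ``(n_features,)`` for ``mlp``, ``(timesteps,
    n_channels)`` for ``lstm`` and ``(n_raw_samples, n_channels)`` for
    ``cnn``/``clstm``.
    """

    arch: str
    input_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        need = 1 if self.arch == "mlp" else 2
        if len(self.input_shape) != need or any(s < 1 for s in self.input_shape):
            raise ValueError(
                f"{self.arch} expects input_shape of {need} positive ints, "
                f"got {self.input_shape}"
            )

    @property
    def layout(self) -> str:
        return {"mlp": "mlp_vector", "lstm": "lstm_sequence",
                "cnn": "raw_image", "clstm": "raw_image"}[self.arch]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings (Adam, stepwise LR drop)."""

    lr: float = 0.001
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.2
    batch_size: int = 256
    shuffle_each_epoch: bool = True
    n_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0 or self.batch_size < 1:
            raise ValueError("lr must be >= 0 and batch size >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.lr * self.lr_drop_factor ** (epoch // self.lr_drop_period)


def cnn_shape_trace(h: int, w: int) -> list[tuple[int, int, int]]:
    """(height, width, filters) after each of the four convolution blocks."""
    out = []
    for f in CNN_FILTERS:
        h = nn.AvgPool2D.out_size(h)
        w = nn.AvgPool2D.out_size(w)
        out.append((h, w, f))
    return out


def build_network(spec: DnnSpec, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Instantiate an untrained network with Glorot-initialised weights.

    Two builds with the same seed produce identical initial parameters.
    """
    rng = np.random.default_rng(seed)
    L: list[tuple[str, nn.Layer]] = []
    if spec.arch == "mlp":
        (f,) = spec.input_shape
        L.append(("fc1", nn.Dense(f, MLP_FC[0], rng, dtype)))  # linear input map
        L.append(("fc2", nn.Dense(MLP_FC[0], MLP_FC[1], rng, dtype)))
        L.append(("fc2_relu", nn.ReLU()))
        L.append(("fc3", nn.Dense(MLP_FC[1], MLP_FC[2], rng, dtype)))
        L.append(("fc3_relu", nn.ReLU()))
        L.append(("out", nn.Dense(MLP_FC[2], 1, rng, dtype)))
    elif spec.arch == "lstm":
        t, c = spec.input_shape
        L.append(("fc1", nn.Dense(c, LSTM_FC_IN, rng, dtype)))  # per-timestep, linear
        L.append(("lstm", nn.LSTM(LSTM_FC_IN, LSTM_UNITS, rng, dtype)))
        L.append(("fc2", nn.Dense(LSTM_UNITS, LSTM_FC_OUT, rng, dtype)))
        L.append(("fc2_relu", nn.ReLU()))
        L.append(("out", nn.Dense(LSTM_FC_OUT, 1, rng, dtype)))
    else:
        h, w = spec.input_shape
        c_in = 1
        for b, f in enumerate(CNN_FILTERS, start=1):
            L.append((f"conv{b}", nn.Conv2D(c_in, f, rng, dtype=dtype)))
            if b <= 3:  # batch norm omitted from block 4
                L.append((f"bn{b}", nn.BatchNorm(f, dtype)))
            L.append((f"conv{b}_relu", nn.ReLU()))
            L.append((f"pool{b}", nn.AvgPool2D()))
            c_in = f
        hh, ww, ff = cnn_shape_trace(h, w)[-1]
        if spec.arch == "cnn":
            L.append(("flatten", nn.Flatten()))
            L.append(("dropout", nn.Dropout(DROPOUT_RATE)))
            L.append(("fc1", nn.Dense(hh * ww * ff, CNN_FC, rng, dtype)))
            L.append(("fc1_relu", nn.ReLU()))
            L.append(("out", nn.Dense(CNN_FC, 1, rng, dtype)))
        else:  # clstm
            L.append(("to_seq", nn.ToSequence()))
            L.append(("lstm", nn.LSTM(ww * ff, CLSTM_UNITS, rng, dtype)))
            L.append(("dropout", nn.Dropout(DROPOUT_RATE)))
            L.append(("fc1", nn.Dense(CLSTM_UNITS, CNN_FC, rng, dtype)))
            L.append(("fc1_relu", nn.ReLU()))
            L.append(("out", nn.Dense(CNN_FC, 1, rng, dtype)))
    return nn.Network(L, arch=spec.arch, input_shape=spec.input_shape)


def _prep_input(spec: DnnSpec, X: np.ndarray, dtype=np.float32) -> np.ndarray:
    X = np.asarray(X, dtype=dtype)
    if spec.arch == "mlp":
        if X.shape[1:] != spec.input_shape:
            raise ValueError(
                f"mlp expects vectors of shape {spec.input_shape}, got {X.shape[1:]}"
            )
        return X
    if spec.arch == "lstm":
        if X.shape[1:] != spec.input_shape:
            raise ValueError(
                f"lstm expects sequences of shape {spec.input_shape}, got {X.shape[1:]}"
            )
        return X
    if X.shape[1:3] != spec.input_shape:
        raise ValueError(
            f"{spec.arch} expects images of shape {spec.input_shape}, got {X.shape[1:]}"
        )
    return X[..., None] if X.ndim == 3 else X


def train_network(
    network: nn.Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    *,
    spec: DnnSpec | None = None,
) -> list[float]:
    """Train in place with Adam + stepwise LR schedule; returns per-epoch
    mean training loss.  Deterministic given ``config.seed``."""
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if spec is not None:
        X = _prep_input(spec, X)
    y = np.asarray(y, dtype=X.dtype)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(lr=config.lr, drop_period=config.lr_drop_period,
                  drop_factor=config.lr_drop_factor)
    n = X.shape[0]
    history: list[float] = []
    for epoch in range(config.n_epochs):
        idx = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses = []
        for k in range(0, n, config.batch_size):
            b = idx[k : k + config.batch_size]
            yhat = network.forward(X[b], train=True, rng=rng)[:, 0]
            err = yhat - y[b]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {k // config.batch_size}; "
                    "try a lower learning rate or check input scaling"
                )
            losses.append(loss)
            g = (2.0 * err / err.shape[0])[:, None].astype(X.dtype)
            network.backward(g)
            opt.step(network, epoch)
        history.append(float(np.mean(losses)))
    return history


class DnnTorque:
    """Deep windowed torque regressor (model object).

    Construct from a window batch (``X``: layout depends on ``arch``) and
    %MVT targets ``y``; ``fit`` trains a freshly built network, or
    continues from ``initial_weights`` when given (used by transfer
    learning).
    """

    def __init__(self, X, y, spec: DnnSpec):
        self.spec = spec
        self.X = _prep_input(spec, np.asarray(X))
        self.y = np.asarray(y, dtype=np.float32)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have equal batch sizes")

    @classmethod
    def from_windows(cls, windows: WindowSet, arch: str) -> "DnnTorque":
        spec = DnnSpec(arch=arch, input_shape=tuple(windows.X.shape[1:3])
                       if arch in ("cnn", "clstm", "lstm") else (windows.X.shape[1],))
        expected = spec.layout
        if windows.layout != expected:
            raise ValueError(
                f"{arch} needs {expected} windows, got {windows.layout}"
            )
        return cls(windows.X, windows.y, spec)

    def fit(self, config: TrainConfig = TrainConfig(), *,
            network: nn.Network | None = None) -> "DnnTorqueResults":
        net = network if network is not None else build_network(self.spec, seed=config.seed)
        history = train_network(net, self.X, self.y, config)
        return DnnTorqueResults(model=self, network=net, config=config,
                                loss_history=history)


@dataclass
class DnnTorqueResults:
    """A trained deep regressor with its loss history."""

    model: DnnTorque
    network: nn.Network
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return self.network.predict(_prep_input(self.model.spec, X))

    def summary(self) -> str:
        lines = [self.network.summary()]
        lines.append(
            f"  trained {len(self.loss_history)} epochs "
            f"(final loss {self.loss_history[-1]:.4f})"
            if self.loss_history else "  untrained"
        )
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Per-epoch training loss on a log scale (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.semilogy(np.arange(1, len(self.loss_history) + 1), self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training MSE (%MVT$^2$)")
        return ax
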