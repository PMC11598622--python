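"""Cross-joint transfer learning: pre-train, bridge dimensions, fine-tune.

A model pre-trained on the source joint (elbow: 8 channels at 4096 Hz) is
re-used as the starting point for the target joint (hand--wrist: 16
channels at 2048 Hz) and fine-tuned with a smaller learning rate (0.0005).

Input-dimension bridging:

* ``mlp``/``lstm`` — the first FC layer is the input transformation matrix
  and is *excluded* from the pre-trained bundle; at adaptation a fresh,
  randomly initialised first FC layer of the target's input width is
  trained from scratch while the deeper layers start from the bundle.
* ``cnn``/``clstm`` — convolution kernels are fixed-size (3x3) and slide
  over images of any size, so all convolution blocks (and the C-LSTM's
  LSTM, whose post-convolution feature width is domain invariant) transfer
  verbatim.  A dense layer whose flattened input width differs between
  domains (the CNN's FC after flatten: 1600x8 and 800x16 images pool to
  different time lengths) cannot reuse its weights and is re-initialised;
  the adaptation report records per-layer status.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .models import DnnSpec, DnnTorque, TrainConfig, build_network, train_network
from .protocols import FRAME_RATE

__all__ = [
    "WeightsBundle", "TLConfig", "pretrain", "adapt", "finetune",
    "truncation_frames", "write_transfer_report",
]

DATA_SIZES_S = (40, 35, 30, 25, 20, 15, 10, 5)
"""Training/fine-tuning data sizes per trial (s) for the data-size sweep."""

#: layers whose weights are the input transformation and never transfer
_INPUT_LAYERS = {"mlp": ("fc1",), "lstm": ("fc1",), "cnn": (), "clstm": ()}


@dataclass
class WeightsBundle:
    """Architecture-tagged trained weights with transfer metadata."""

    arch: str
    tensors: dict[str, np.ndarray]
    source_input_shape: tuple[int, ...]
    seed: int
    config_hash: str = ""

    def layer_names(self) -> list[str]:
        return sorted({k.split(".")[0] for k in self.tensors})

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.tensors):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.tensors[k]).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        meta = {
            "arch": self.arch,
            "source_input_shape": list(self.source_input_shape),
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.tensors)

    @classmethod
    def load(cls, path) -> "WeightsBundle":
        with np.load(path) as z:
            meta = json.loads(z["__meta__"].tobytes().decode())
            tensors = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(
            arch=meta["arch"], tensors=tensors,
            source_input_shape=tuple(meta["source_input_shape"]),
            seed=meta["seed"], config_hash=meta["config_hash"],
        )


@dataclass(frozen=True)
class TLConfig:
    """Fine-tuning settings: smaller learning rate, reduced data size."""

    finetune_lr: float = 0.0005
    data_size_s: float = 40.0
    n_epochs: int = 30
    batch_size: int = 256
    lr_drop_period: int = 10
    lr_drop_factor: float = 0.2
    seed: int = 0

    def as_train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.finetune_lr, lr_drop_period=self.lr_drop_period,
            lr_drop_factor=self.lr_drop_factor, batch_size=self.batch_size,
            n_epochs=self.n_epochs, seed=self.seed,
        )


def _config_hash(config: TrainConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def pretrain(arch: str, X, y, config: TrainConfig,
             input_shape: tuple[int, ...] | None = None) -> WeightsBundle:
    """Train ``arch`` on aggregated source-domain windows; return the
    transferable weights (input FC excluded for ``mlp``/``lstm``)."""
    if np.asarray(X).shape[0] == 0:
        raise ValueError("empty source training set")
    if input_shape is None:
        Xa = np.asarray(X)
        input_shape = (Xa.shape[1],) if arch == "mlp" else tuple(Xa.shape[1:3])
    spec = DnnSpec(arch=arch, input_shape=input_shape)
    result = DnnTorque(X, y, spec).fit(config)
    weights = result.network.get_weights()
    excluded = _INPUT_LAYERS[arch]
    tensors = {k: v for k, v in weights.items()
               if k.split(".")[0] not in excluded}
    return WeightsBundle(
        arch=arch, tensors=tensors, source_input_shape=spec.input_shape,
        seed=config.seed, config_hash=_config_hash(config),
    )


def adapt(bundle: WeightsBundle, target_input_shape: tuple[int, ...],
          seed: int = 0) -> tuple[nn.Network, dict[str, str]]:
    """Initialise a target-domain network from a pre-trained bundle.

    Every bundle tensor whose shape matches the target network is copied
    bit-for-bit; a dense layer whose input width differs between domains is
    left at its fresh random initialisation.  Returns the network and a
    per-layer report (``transferred`` / ``reinitialized`` / ``new``).
    """
    if bundle.arch not in _INPUT_LAYERS:
        raise ValueError(f"bundle has unknown architecture {bundle.arch!r}")
    spec = DnnSpec(arch=bundle.arch, input_shape=tuple(target_input_shape))
    net = build_network(spec, seed=seed)
    target_keys = net.get_weights()
    report: dict[str, str] = {}
    usable: dict[str, np.ndarray] = {}
    for lname in net.layer_names():
        keys = [k for k in target_keys if k.split(".")[0] == lname]
        if not keys:
            continue  # activation/pool layers carry no weights
        in_bundle = [k for k in keys if k in bundle.tensors]
        if not in_bundle:
            report[lname] = "new"
            continue
        if all(bundle.tensors[k].shape == target_keys[k].shape for k in in_bundle):
            usable.update({k: bundle.tensors[k] for k in in_bundle})
            report[lname] = "transferred"
        else:
            report[lname] = "reinitialized"
    net.set_weights(usable)
    return net, report


def finetune(network: nn.Network, X, y, config: TLConfig,
             spec: DnnSpec | None = None) -> tuple[nn.Network, list[float]]:
    """Fine-tune all layers at the reduced learning rate.

    ``config.data_size_s`` is bookkeeping here — callers truncate the
    training windows before this point.  Zero epochs is a no-op.
    """
    tc = config.as_train_config()
    if tc.n_epochs == 0:
        return network, []
    if spec is None:
        spec = DnnSpec(arch=network.arch, input_shape=network.input_shape)
    from .models import _prep_input

    history = train_network(network, _prep_input(spec, np.asarray(X)), np.asarray(y), tc)
    return network, history


def truncation_frames(data_size_s: float) -> int:
    """Envelope frames in the first ``data_size_s`` seconds (floor)."""
    if data_size_s <= 0:
        raise ValueError("data size must be positive")
    return int(np.floor(data_size_s * FRAME_RATE))


def write_transfer_report(report: dict[str, str], path) -> None:
    """Dump the per-layer transfer status as ``transfer-report.json``."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
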