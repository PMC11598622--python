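"""Desk-scale study conditions for property checks and demonstrations.

The full recording protocols (65 source subjects at 4096 Hz, 40 s trials,
16 channels, 25 ms window increments, 30-epoch training) are far beyond a
single-CPU property-test budget, so direction-only replications run on
scaled-down protocol variants that preserve every structural feature the
analysis depends on: two domains with different channel counts and
sampling rates (both integer multiples of 40.96 Hz), agonist/antagonist
gain structure, bandlimited tracking targets, calibration and MVT trials,
four dynamic trials per DoF for two-fold cross-validation, and the same
window grid.

Scaled conditions (fixed once; see docs/methods.md):

* ``TARGET_DESK`` — 4 channels at 204.8 Hz (decimation 5), one wrist-like
  DoF, +/-30 %MVT at 0.75 Hz, 10 s dynamic trials.
* ``SOURCE_DESK`` — 2 channels at 409.6 Hz (decimation 10), one
  elbow-like DoF, +/-50 %MVT at 1 Hz, 8 s dynamic trials, 2 trials per
  subject (pre-training aggregates subjects, not trials).

Raw-image architectures use a coarser window increment than the envelope
architectures to bound convolution cost; training budgets are scaled so
each fit still takes a few hundred optimiser steps.
"""

from __future__ import annotations

from .models import TrainConfig
from .protocols import DomainProtocol

TARGET_DESK = DomainProtocol(
    name="target-desk",
    n_channels=4,
    fs=204.8,
    dofs=("wrist_ef",),
    trials_per_dof=4,
    trial_duration=10.0,
    target_bandlimit=0.75,
    target_range=(30.0,),
    calibration_duration=3.0,
    mvt_duration=3.0,
)

SOURCE_DESK = DomainProtocol(
    name="source-desk",
    n_channels=2,
    fs=409.6,
    dofs=("elbow_ef",),
    trials_per_dof=2,
    trial_duration=8.0,
    target_bandlimit=1.0,
    target_range=(50.0,),
    calibration_duration=3.0,
    mvt_duration=3.0,
)

#: per-architecture (window increment ms, training config) at desk scale.
#: batch sizes are scaled down with the window counts so each LR plateau
#: still spans on the order of a hundred optimiser steps, as it does at
#: full scale with 256-sample batches
DESK_TRAINING: dict[str, tuple[float, TrainConfig | None]] = {
    "fir": (150.0, None),
    "mlp": (25.0, TrainConfig(n_epochs=30, batch_size=16)),
    "lstm": (50.0, TrainConfig(n_epochs=30, batch_size=16)),
    "cnn": (150.0, TrainConfig(n_epochs=30, batch_size=16)),
    "clstm": (150.0, TrainConfig(n_epochs=30, batch_size=16)),
}

#: pre-training budgets (source domain, aggregated subjects)
DESK_PRETRAIN: dict[str, TrainConfig] = {
    "mlp": TrainConfig(n_epochs=30, batch_size=256),
    "lstm": TrainConfig(n_epochs=20, batch_size=256),
    "cnn": TrainConfig(n_epochs=10, batch_size=64),
    "clstm": TrainConfig(n_epochs=10, batch_size=64),
}

#: desk analogues of the large/small per-trial training-data sizes
#: (1/4-scale of 40 s trials: 8 s ~ full data, 2.5 s ~ the <=10 s regime)
DESK_DATA_SIZES = (8.0, 2.5)

#: fine-tuning runs at half the learning rate, so the desk budget doubles
#: the epochs and the LR-drop period to do equal optimisation work with
#: the non-TL arm (at full scale both arms converge and this is moot)
DESK_FINETUNE = TrainConfig(lr=0.0005, n_epochs=60, lr_drop_period=20,
                            batch_size=16)


def desk_increment(arch: str) -> float:
    return DESK_TRAINING[arch][0]


def desk_train_config(arch: str, seed: int = 0) -> TrainConfig | None:
    inc, tc = DESK_TRAINING[arch]
    if tc is None:
        return None
    return TrainConfig(
        lr=tc.lr, lr_drop_period=tc.lr_drop_period, lr_drop_factor=tc.lr_drop_factor,
        batch_size=tc.batch_size, shuffle_each_epoch=tc.shuffle_each_epoch,
        n_epochs=tc.n_epochs, seed=seed,
    )


def desk_finetune_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        lr=DESK_FINETUNE.lr, lr_drop_period=DESK_FINETUNE.lr_drop_period,
        lr_drop_factor=DESK_FINETUNE.lr_drop_factor,
        batch_size=DESK_FINETUNE.batch_size, n_epochs=DESK_FINETUNE.n_epochs,
        seed=seed,
    )
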