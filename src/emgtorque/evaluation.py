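"""%MVT RMSE scoring, two-fold cross-validation, and sweep drivers.

Evaluation protocol: per subject and DoF there are four dynamic trials;
fold A trains on trials {1, 2} and tests on {3, 4}, fold B the reverse.
Every model estimates each DoF separately.  The score is the root mean
square error between estimated and true torque in %MVT, with the first and
last second of every test trial omitted (filter start-up transients; the
omission is applied to raw-input models too, for consistency).  A
subject's performance is the arithmetic mean over its trials x DoFs.

The sweep drivers reproduce the two study designs: the window-length sweep
(eight lengths, 98--781 ms) and the training-data-size sweep (TL vs
non-TL arms at 40..5 s per trial), emitting tidy per-trial tables plus
mean +/- SD summaries over subjects.  A master seed fans out to
per-(subject, arch, condition) seeds through a stable hash so TL and
non-TL arms are paired.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .models import DnnSpec, DnnTorque, FirTorque, TrainConfig
from .preprocessing import (
    compute_gains,
    condition_torque,
    extract_amplitude,
    measure_mvt,
)
from .protocols import FRAME_RATE, DomainProtocol
from .synth import Dataset, SubjectData
from .transfer import TLConfig, WeightsBundle, adapt, finetune, truncation_frames
from .windowing import (
    WINDOW_LENGTHS_MS,
    WindowSpec,
    make_image_input,
    make_mlp_input,
    make_sequence_input,
)

__all__ = [
    "rmse_pct_mvt", "run_cv", "window_sweep", "data_size_sweep",
    "derive_seed", "subject_means", "condition_summary",
    "prepare_subject_dof", "training_windows_for_dataset",
]


def rmse_pct_mvt(estimate, truth, frame_rate: float = FRAME_RATE,
                 omit_s: float = 1.0) -> float:
    """RMSE (%MVT) over the trace interior, edges of ``omit_s`` s dropped."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have equal lengths")
    k = int(round(omit_s * frame_rate))
    if estimate.shape[0] <= 2 * k:
        raise ValueError("trace too short for the edge omission")
    e = estimate[k : estimate.shape[0] - k] - truth[k : truth.shape[0] - k]
    return float(np.sqrt(np.mean(e**2)))


def _rmse_windows(pred, y, end_frames, n_frames, frame_rate=FRAME_RATE,
                  omit_s: float = 1.0) -> float:
    """Window-level RMSE keeping windows whose target frame lies in the
    trace interior."""
    k = int(round(omit_s * frame_rate))
    keep = (end_frames >= k) & (end_frames < n_frames - k)
    if not np.any(keep):
        raise ValueError("no windows survive the edge omission")
    e = np.asarray(pred)[keep] - np.asarray(y)[keep]
    return float(np.sqrt(np.mean(e**2)))


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-condition seed below 2**31 from a master seed."""
    h = hashlib.sha256(":".join([str(master_seed), *map(str, parts)]).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# per-subject preparation
# --------------------------------------------------------------------------

def prepare_subject_dof(
    subject: SubjectData,
    protocol: DomainProtocol,
    dof: str,
    *,
    features: str = "extracted",
):
    """Normalise one subject/DoF: per-trial amplitude frames, %MVT torque
    frames and gain-scaled raw EMG for the dynamic trials.

    ``features="latent"`` substitutes the generator's latent amplitudes for
    the extracted envelope (a diagnostic mode for recovery oracles).
    """
    cal_pos = subject.get(dof, "calibration_pos")[0]
    cal_neg = subject.get(dof, "calibration_neg")[0]
    mvt_pos = measure_mvt(subject.get(dof, "mvt_pos")[0])
    mvt_neg = measure_mvt(subject.get(dof, "mvt_neg")[0])
    gains = compute_gains(cal_pos, cal_neg, mvt_pos, mvt_neg, dof=dof)
    prepared = []
    for trial in subject.get(dof, "dynamic"):
        if features == "latent":
            env = trial.latent_amplitude
        elif features == "extracted":
            env = extract_amplitude(
                trial.emg, trial.fs,
                channel_gains=gains.emg_gain, line_freq=protocol.line_freq,
            ).values
        else:
            raise ValueError(f"unknown feature mode {features!r}")
        torque = condition_torque(trial.torque, trial.fs,
                                  torque_gain=gains.torque_gain)
        n = min(env.shape[0], torque.shape[0])
        raw = trial.emg * gains.emg_gain[None, :]
        prepared.append({"envelope": env[:n], "torque": torque[:n], "raw": raw,
                         "trial_id": trial.trial_id})
    return prepared, gains


def _windows_for(arch: str, prep: dict, spec: WindowSpec, fs: float,
                 n_frames: int | None = None):
    env, torque, raw = prep["envelope"], prep["torque"], prep["raw"]
    if n_frames is not None:
        D = int(round(fs / FRAME_RATE))
        env, torque, raw = env[:n_frames], torque[:n_frames], raw[: n_frames * D]
    if arch == "mlp":
        return make_mlp_input(env, spec, torque)
    if arch == "lstm":
        return make_sequence_input(env, spec, torque)
    if arch in ("cnn", "clstm"):
        return make_image_input(raw, spec, fs, torque)
    raise ValueError(f"unknown architecture {arch!r}")


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def run_cv(
    subject: SubjectData,
    protocol: DomainProtocol,
    arch: str,
    *,
    window_ms: float = 391.0,
    increment_ms: float = 25.0,
    tl_bundle: WeightsBundle | None = None,
    data_size_s: float | None = None,
    data_offset_s: float = 1.0,
    train_config: TrainConfig | None = None,
    finetune_config: TrainConfig | None = None,
    seed: int = 0,
    features: str = "extracted",
    omit_s: float = 1.0,
) -> pd.DataFrame:
    """Two-fold cross-validation for one subject; one RMSE row per
    (DoF, fold, test trial).

    ``arch`` is ``"fir"`` or one of the DNN tags.  With ``tl_bundle`` the
    network starts from the pre-trained weights and is fine-tuned at the
    reduced learning rate; otherwise training starts from random
    initialisation.  ``data_size_s`` truncates each training trial to its
    first ``data_size_s`` seconds (taken after ``data_offset_s`` to skip
    the filter start-up region).
    """
    spec = WindowSpec(window_ms, increment_ms)
    rows = []
    for dof in protocol.dofs:
        prepared, _ = prepare_subject_dof(subject, protocol, dof, features=features)
        if len(prepared) != 4:
            raise ValueError(
                f"two-fold CV needs 4 dynamic trials per DoF, got {len(prepared)}"
            )
        if data_size_s is not None:
            total = data_offset_s + data_size_s
            if total * FRAME_RATE > min(p["envelope"].shape[0] for p in prepared):
                raise ValueError(
                    f"data size {data_size_s} s (+{data_offset_s} s offset) "
                    "exceeds trial length"
                )
        for fold, (train_idx, test_idx) in enumerate(
            (((0, 1), (2, 3)), ((2, 3), (0, 1)))
        ):
            train = [prepared[i] for i in train_idx]
            test = [prepared[i] for i in test_idx]
            cond_seed = derive_seed(seed, subject.subject_id, dof, arch, fold)
            if arch == "fir":
                predict = _fit_fold_fir(train, spec, data_size_s, data_offset_s)
            else:
                predict = _fit_fold_dnn(
                    arch, train, spec, protocol.fs, tl_bundle, data_size_s,
                    data_offset_s, train_config, finetune_config, cond_seed,
                )
            for t in test:
                rows.append({
                    "subject": subject.subject_id, "dof": dof, "fold": fold,
                    "trial": t["trial_id"], "arch": arch,
                    "window_ms": window_ms,
                    "tl": tl_bundle is not None,
                    "data_size_s": data_size_s if data_size_s is not None else np.nan,
                    "rmse": predict(t, omit_s),
                })
    return pd.DataFrame(rows)


def _truncate_slices(data_size_s, data_offset_s):
    if data_size_s is None:
        return None, None
    start = int(np.floor(data_offset_s * FRAME_RATE))
    return start, start + truncation_frames(data_size_s)


def _fit_fold_fir(train, spec: WindowSpec, data_size_s, data_offset_s):
    order = spec.frames - 1
    lo, hi = _truncate_slices(data_size_s, data_offset_s)
    envs = [t["envelope"][lo:hi] for t in train]
    torqs = [t["torque"][lo:hi] for t in train]
    res = FirTorque(envs, torqs, order=order).fit()

    def predict(t, omit_s):
        est = res.predict(t["envelope"])
        return rmse_pct_mvt(est, t["torque"], omit_s=omit_s)

    return predict


def _fit_fold_dnn(arch, train, spec, fs, tl_bundle, data_size_s, data_offset_s,
                  train_config, finetune_config, cond_seed):
    lo, hi = _truncate_slices(data_size_s, data_offset_s)
    n_frames = None if hi is None else hi
    batches = []
    for t in train:
        w = _windows_for(arch, t, spec, fs, n_frames=n_frames)
        if lo is not None:
            keep = w.starts >= lo
            w.X, w.y, w.starts = w.X[keep], w.y[keep], w.starts[keep]
        batches.append(w)
    X = np.concatenate([b.X for b in batches])
    y = np.concatenate([b.y for b in batches])
    tc = train_config if train_config is not None else TrainConfig()
    if tl_bundle is not None:
        input_shape = (X.shape[1],) if arch == "mlp" else tuple(X.shape[1:3])
        net, _ = adapt(tl_bundle, input_shape, seed=cond_seed)
        fc = finetune_config
        tl = TLConfig(
            finetune_lr=fc.lr if fc is not None else 0.0005,
            data_size_s=data_size_s if data_size_s is not None else 0.0,
            n_epochs=fc.n_epochs if fc is not None else tc.n_epochs,
            batch_size=fc.batch_size if fc is not None else tc.batch_size,
            lr_drop_period=fc.lr_drop_period if fc is not None else tc.lr_drop_period,
            lr_drop_factor=fc.lr_drop_factor if fc is not None else tc.lr_drop_factor,
            seed=cond_seed,
        )
        dspec = DnnSpec(arch=arch, input_shape=input_shape)
        net, _ = finetune(net, X, y, tl, spec=dspec)
        results_net = net
        dnn_spec = dspec
    else:
        model = DnnTorque(X, y, DnnSpec(
            arch=arch, input_shape=(X.shape[1],) if arch == "mlp" else tuple(X.shape[1:3])
        ))
        tc_seeded = TrainConfig(
            lr=tc.lr, lr_drop_period=tc.lr_drop_period,
            lr_drop_factor=tc.lr_drop_factor, batch_size=tc.batch_size,
            shuffle_each_epoch=tc.shuffle_each_epoch, n_epochs=tc.n_epochs,
            seed=cond_seed,
        )
        fitted = model.fit(tc_seeded)
        results_net = fitted.network
        dnn_spec = model.spec

    def predict(t, omit_s):
        w = _windows_for(arch, t, spec, fs)
        from .models import _prep_input

        pred = results_net.predict(_prep_input(dnn_spec, w.X))
        end_frames = w.starts + w.frames - 1
        return _rmse_windows(pred, w.y, end_frames, t["torque"].shape[0],
                             omit_s=omit_s)

    return predict


# --------------------------------------------------------------------------
# report helpers and sweep drivers
# --------------------------------------------------------------------------

_CONDITION_COLS = ["arch", "window_ms", "tl", "data_size_s"]


def subject_means(report: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean RMSE over trials x DoFs, per condition."""
    return (
        report.groupby(["subject", *_CONDITION_COLS], dropna=False)["rmse"]
        .mean().reset_index()
    )


def condition_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD over subjects of the per-subject means."""
    per_subj = subject_means(report)
    return (
        per_subj.groupby(_CONDITION_COLS, dropna=False)["rmse"]
        .agg(mean="mean", sd="std", n_subjects="count").reset_index()
    )


def training_windows_for_dataset(
    dataset: Dataset,
    arch: str,
    window_spec: WindowSpec,
    *,
    features: str = "extracted",
):
    """Aggregate every subject's dynamic-trial windows (for pre-training)."""
    Xs, ys = [], []
    proto = dataset.protocol
    for sid in dataset.subject_ids:
        subject = dataset.subjects[sid]
        for dof in proto.dofs:
            prepared, _ = prepare_subject_dof(subject, proto, dof, features=features)
            for t in prepared:
                w = _windows_for(arch, t, window_spec, proto.fs)
                Xs.append(w.X)
                ys.append(w.y)
    return np.concatenate(Xs), np.concatenate(ys)


def window_sweep(
    dataset: Dataset,
    archs,
    *,
    lengths=WINDOW_LENGTHS_MS,
    increment_ms: float = 25.0,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    features: str = "extracted",
) -> pd.DataFrame:
    """Evaluate every (arch, window length) over all subjects (non-TL)."""
    frames = []
    for arch in archs:
        for ms in lengths:
            for sid in dataset.subject_ids:
                frames.append(run_cv(
                    dataset.subjects[sid], dataset.protocol, arch,
                    window_ms=ms, increment_ms=increment_ms,
                    train_config=train_config,
                    seed=derive_seed(seed, "window_sweep", arch, ms),
                    features=features,
                ))
    return pd.concat(frames, ignore_index=True)


def data_size_sweep(
    dataset: Dataset,
    archs,
    bundles: dict[str, WeightsBundle],
    *,
    sizes=(40, 35, 30, 25, 20, 15, 10, 5),
    window_ms: float = 391.0,
    increment_ms: float = 25.0,
    train_config: TrainConfig | None = None,
    finetune_config: TrainConfig | None = None,
    seed: int = 0,
    features: str = "extracted",
) -> pd.DataFrame:
    """TL and non-TL arms at each training data size (paired seeds)."""
    frames = []
    for arch in archs:
        for size in sizes:
            cond_seed = derive_seed(seed, "data_size_sweep", arch, size)
            for tl in (False, True):
                bundle = bundles.get(arch) if tl else None
                if tl and bundle is None:
                    raise ValueError(f"no pre-trained bundle for arch {arch!r}")
                for sid in dataset.subject_ids:
                    frames.append(run_cv(
                        dataset.subjects[sid], dataset.protocol, arch,
                        window_ms=window_ms, increment_ms=increment_ms,
                        tl_bundle=bundle, data_size_s=size,
                        train_config=train_config,
                        finetune_config=finetune_config,
                        seed=cond_seed, features=features,
                    ))
    return pd.concat(frames, ignore_index=True)


def plot_condition_summary(report, ax=None):
    """Bar chart of mean +/- SD %MVT RMSE per condition (matplotlib)."""
    import matplotlib.pyplot as plt

    summ = condition_summary(report)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.9 * len(summ), 3.2))
    labels = [
        f"{r.arch}\n{r.window_ms:g} ms" + (" TL" if r.tl else "")
        + (f"\n{r.data_size_s:g} s" if np.isfinite(r.data_size_s) else "")
        for r in summ.itertuples()
    ]
    ax.bar(range(len(summ)), summ["mean"], yerr=summ["sd"].fillna(0.0),
           capsize=3, color="steelblue")
    ax.set_xticks(range(len(summ)), labels, fontsize=8)
    ax.set_ylabel("RMSE (%MVT)")
    return ax
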