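"""HDF5 dataset container and report I/O.

Layout::

    /subjects/<id>/<dof>/<trial_kind>/<trial_id>/emg      [n, channels]
    /subjects/<id>/<dof>/<trial_kind>/<trial_id>/torque   [n]
        (attrs: fs, channels, units; latent_amplitude / latent_drive
         datasets are stored alongside when present)
    /truth/<id>/{gain_pos, gain_neg, kernels}             (+ scalar attrs)

Root attributes carry the generating protocol so a dataset round-trips
without external metadata.
"""

from __future__ import annotations

import h5py
import numpy as np

from .protocols import DomainProtocol, SubjectGroundTruth, Trial
from .synth import Dataset, SubjectData

__all__ = ["save_dataset", "load_dataset", "write_report"]


def save_dataset(dataset: Dataset, path) -> None:
    proto = dataset.protocol
    with h5py.File(path, "w") as f:
        f.attrs["protocol_name"] = proto.name
        f.attrs["n_channels"] = proto.n_channels
        f.attrs["fs"] = proto.fs
        f.attrs["dofs"] = list(proto.dofs)
        f.attrs["trials_per_dof"] = proto.trials_per_dof
        f.attrs["trial_duration"] = proto.trial_duration
        f.attrs["target_bandlimit"] = proto.target_bandlimit
        f.attrs["target_range"] = list(proto.target_range)
        f.attrs["line_freq"] = proto.line_freq
        f.attrs["calibration_duration"] = proto.calibration_duration
        f.attrs["mvt_duration"] = proto.mvt_duration
        for sid, subj in dataset.subjects.items():
            for trial in subj.trials:
                g = f.create_group(
                    f"subjects/{sid}/{trial.dof}/{trial.kind}/{trial.trial_id}"
                )
                g.create_dataset("emg", data=trial.emg)
                g.create_dataset("torque", data=trial.torque)
                g.attrs["fs"] = trial.fs
                g.attrs["channels"] = trial.n_channels
                g.attrs["units"] = "raw"
                if trial.latent_amplitude is not None:
                    g.create_dataset("latent_amplitude", data=trial.latent_amplitude)
                if trial.latent_drive is not None:
                    g.create_dataset("latent_drive", data=trial.latent_drive)
            t = subj.truth
            gt = f.create_group(f"truth/{sid}")
            gt.create_dataset("gain_pos", data=t.gain_pos)
            gt.create_dataset("gain_neg", data=t.gain_neg)
            gt.create_dataset("kernels", data=t.kernels)
            gt.attrs["baseline_amplitude"] = t.baseline_amplitude
            gt.attrs["saturation_coeff"] = t.saturation_coeff
            gt.attrs["noise_sd"] = t.noise_sd
            gt.attrs["line_amplitude"] = t.line_amplitude
            gt.attrs["sensor_noise_sd"] = t.sensor_noise_sd


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        proto = DomainProtocol(
            name=str(f.attrs["protocol_name"]),
            n_channels=int(f.attrs["n_channels"]),
            fs=float(f.attrs["fs"]),
            dofs=tuple(str(d) for d in f.attrs["dofs"]),
            trials_per_dof=int(f.attrs["trials_per_dof"]),
            trial_duration=float(f.attrs["trial_duration"]),
            target_bandlimit=float(f.attrs["target_bandlimit"]),
            target_range=tuple(float(r) for r in f.attrs["target_range"]),
            line_freq=float(f.attrs["line_freq"]),
            calibration_duration=float(f.attrs["calibration_duration"]),
            mvt_duration=float(f.attrs["mvt_duration"]),
        )
        ds = Dataset(protocol=proto)
        for sid in sorted(f["subjects"]):
            gt = f["truth"][sid]
            truth = SubjectGroundTruth(
                gain_pos=gt["gain_pos"][()],
                gain_neg=gt["gain_neg"][()],
                baseline_amplitude=float(gt.attrs["baseline_amplitude"]),
                kernels=gt["kernels"][()],
                saturation_coeff=float(gt.attrs["saturation_coeff"]),
                noise_sd=float(gt.attrs["noise_sd"]),
                line_amplitude=float(gt.attrs["line_amplitude"]),
                sensor_noise_sd=float(gt.attrs["sensor_noise_sd"]),
            )
            subj = SubjectData(subject_id=sid, truth=truth)
            sg = f["subjects"][sid]
            for dof in sg:
                for kind in sg[dof]:
                    for tid in sg[dof][kind]:
                        g = sg[dof][kind][tid]
                        subj.trials.append(Trial(
                            emg=g["emg"][()],
                            torque=g["torque"][()],
                            fs=float(g.attrs["fs"]),
                            dof=str(dof),
                            kind=str(kind),
                            subject_id=sid,
                            trial_id=int(tid),
                            latent_amplitude=g["latent_amplitude"][()]
                            if "latent_amplitude" in g else None,
                            latent_drive=g["latent_drive"][()]
                            if "latent_drive" in g else None,
                        ))
            subj.trials.sort(key=lambda t: (t.dof, t.kind, t.trial_id))
            ds.subjects[sid] = subj
    return ds


def write_report(df, path) -> None:
    """Tidy CSV with stable row order, for byte-reproducible reports."""
    cols = list(df.columns)
    df.sort_values(cols).to_csv(path, index=False, float_format="%.10g")
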