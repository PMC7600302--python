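"""Cohort persistence (HDF5) and the public MI dataset loader.

A cohort is stored as one HDF5 container with one group per subject
(trials, labels, resting record, sampling rate, timing, montage and the
generating profile as attributes) plus a JSON sidecar with the
generating configuration.

``load_gigadb_subject`` reads the per-subject ``.mat`` layout of the
public 52-subject motor-imagery collection (64 channels at 512 Hz, 7 s
trials, fields ``imagery_left`` / ``imagery_right`` / ``rest`` /
``srate`` / ``n_imagery_trials`` under a top-level ``eeg`` struct).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .containers import (
    LEFT,
    RIGHT,
    EEGRecording,
    Montage,
    TrialSet,
    TrialTiming,
    default_montage,
)
from .synth import SubjectProfile

__all__ = ["save_cohort", "load_cohort", "load_gigadb_subject"]


def save_cohort(path: str | Path,
                trial_sets: Sequence[TrialSet],
                restings: Sequence[EEGRecording] | None = None,
                profiles: Sequence[SubjectProfile] | None = None,
                config: dict | None = None) -> None:
    """Write a cohort to one HDF5 file (+ JSON sidecar with the config)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for m, ts in enumerate(trial_sets):
            grp = h5.create_group(f"subject_{m:03d}")
            grp.create_dataset("trials", data=ts.data, compression="gzip")
            grp.create_dataset("labels", data=np.array(ts.labels, dtype="S8"))
            grp.attrs["fs"] = ts.fs
            grp.attrs["channels"] = list(ts.channels)
            grp.attrs["mi_interval_s"] = list(ts.timing.mi_interval_s)
            grp.attrs["fixation_s"] = list(ts.timing.fixation_s)
            grp.attrs["cue_onset_s"] = ts.timing.cue_onset_s
            grp.attrs["trial_length_s"] = ts.timing.trial_length_s
            if restings is not None:
                grp.create_dataset("resting", data=restings[m].data, compression="gzip")
                grp.attrs["resting_fs"] = restings[m].fs
            if profiles is not None:
                for k, v in dataclasses.asdict(profiles[m]).items():
                    grp.attrs[f"profile_{k}"] = v
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config or {}, indent=2, default=str))


def load_cohort(path: str | Path) -> tuple[list[TrialSet], list[EEGRecording | None],
                                           list[SubjectProfile | None], dict]:
    """Read a cohort written by :func:`save_cohort`."""
    path = Path(path)
    montage = default_montage()
    trial_sets: list[TrialSet] = []
    restings: list[EEGRecording | None] = []
    profiles: list[SubjectProfile | None] = []
    with h5py.File(path, "r") as h5:
        for key in sorted(h5.keys()):
            grp = h5[key]
            timing = TrialTiming(
                fixation_s=tuple(grp.attrs["fixation_s"]),
                cue_onset_s=float(grp.attrs["cue_onset_s"]),
                mi_interval_s=tuple(grp.attrs["mi_interval_s"]),
                trial_length_s=float(grp.attrs["trial_length_s"]),
            )
            channels = tuple(str(c) for c in grp.attrs["channels"])
            mont = montage if set(channels) <= set(montage.labels) else None
            ts = TrialSet(grp["trials"][()],
                          np.array([s.decode() for s in grp["labels"][()]]),
                          float(grp.attrs["fs"]), timing, channels, mont)
            trial_sets.append(ts)
            if "resting" in grp:
                restings.append(EEGRecording(grp["resting"][()],
                                             float(grp.attrs["resting_fs"]),
                                             channels, mont))
            else:
                restings.append(None)
            pk = {k[len("profile_"):]: v for k, v in grp.attrs.items()
                  if k.startswith("profile_")}
            if pk:
                profiles.append(SubjectProfile(
                    subject_id=int(pk["subject_id"]),
                    efficiency=float(pk["efficiency"]),
                    mu_peak_hz=float(pk["mu_peak_hz"]),
                    beta_peak_hz=float(pk["beta_peak_hz"]),
                    mu_amp=float(pk["mu_amp"]),
                    beta_amp=float(pk["beta_amp"]),
                    noise_k1=float(pk["noise_k1"]),
                    noise_k2=float(pk["noise_k2"]),
                    noise_eta=float(pk["noise_eta"]),
                    erd_depth=float(pk["erd_depth"]),
                    seed=int(pk["seed"]),
                ))
            else:
                profiles.append(None)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return trial_sets, restings, profiles, config


# 10-10 labels of the 64-channel cap used by the public collection, in
# recording order (Biosemi-style layout).
_GIGADB_CHANNELS = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)


def load_gigadb_subject(path: str | Path,
                        timing: TrialTiming | None = None,
                        channels: Sequence[str] | None = None,
                        ) -> tuple[TrialSet, EEGRecording]:
    """Load one subject of the public MI collection from its ``.mat`` file.

    Returns the labelled trial set (left/right imagery concatenated) and
    the 60 s resting record.  Imagery arrays are stored as
    (channels, samples*trials) and reshaped using the 7 s trial length.
    """
    from scipy.io import loadmat

    timing = timing or TrialTiming()
    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    eeg = mat["eeg"]
    fs = float(np.atleast_1d(eeg.srate)[0])
    n = int(round(timing.trial_length_s * fs))
    chans = tuple(channels) if channels is not None else _GIGADB_CHANNELS

    def to_trials(arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        n_ch = arr.shape[0]
        n_trials = arr.shape[1] // n
        return arr[:, : n_trials * n].reshape(n_ch, n_trials, n).transpose(1, 0, 2)

    left = to_trials(eeg.imagery_left)
    right = to_trials(eeg.imagery_right)
    data = np.concatenate([left, right], axis=0)
    labels = np.array([LEFT] * left.shape[0] + [RIGHT] * right.shape[0])
    n_ch = data.shape[1]
    ch = chans[:n_ch] if len(chans) >= n_ch else tuple(f"ch{i}" for i in range(n_ch))
    trials = TrialSet(data, labels, fs, timing, ch, None)
    rest = np.asarray(eeg.rest, dtype=float)
    resting = EEGRecording(rest[:n_ch], fs, ch, None)
    return trials, resting
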