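"""Core data containers shared across the pipeline.

The unit of per-subject computation is the :class:`TrialSet` — labelled
multichannel motor-imagery EEG trials with timing metadata.  A single
continuous record (e.g. resting state) is an :class:`EEGRecording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LEFT",
    "RIGHT",
    "TrialTiming",
    "Montage",
    "ChannelConfig",
    "EEGRecording",
    "TrialSet",
    "default_montage",
    "CONFIG_2CH",
    "CONFIG_6CH",
]

#: Class labels for the two motor-imagery tasks.
LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class TrialTiming:
    """Timing of a single MI trial, in seconds from trial onset.

    Default values follow the standard cue-paced paradigm: a 2 s fixation
    baseline, cue at 2 s, and the motor-imagery analysis interval
    2.6–4.6 s within a 7 s trial.
    """

    fixation_s: tuple[float, float] = (0.0, 2.0)
    cue_onset_s: float = 2.0
    mi_interval_s: tuple[float, float] = (2.6, 4.6)
    trial_length_s: float = 7.0

    def __post_init__(self) -> None:
        f0, f1 = self.fixation_s
        m0, m1 = self.mi_interval_s
        if not (0.0 <= f0 < f1 <= self.trial_length_s):
            raise ValueError("fixation interval must be nested in the trial")
        if not (self.cue_onset_s <= m0 < m1 <= self.trial_length_s):
            raise ValueError("MI interval must follow the cue and fit the trial")

    def interval(self, name: str) -> tuple[float, float]:
        """Resolve a named interval ('baseline' or 'mi')."""
        if name == "baseline":
            return self.fixation_s
        if name == "mi":
            return self.mi_interval_s
        raise KeyError(f"unknown interval name {name!r}")


@dataclass(frozen=True)
class Montage:
    """Electrode labels, 2-D scalp coordinates and Laplacian adjacency."""

    labels: tuple[str, ...]
    coordinates: Mapping[str, tuple[float, float]]
    adjacency: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        for ch, neigh in self.adjacency.items():
            for n in neigh:
                if ch not in self.adjacency.get(n, ()):
                    raise ValueError(f"adjacency not symmetric for {ch}/{n}")

    def neighbors(self, label: str) -> tuple[str, ...]:
        return tuple(self.adjacency.get(label, ()))


def _grid_montage(positions: Mapping[str, tuple[float, float]]) -> Montage:
    """Build a montage with nearest-grid-neighbour adjacency (up to 4)."""
    labels = tuple(positions)
    adjacency: dict[str, tuple[str, ...]] = {}
    for ch, (x, y) in positions.items():
        dists = {
            other: np.hypot(x - ox, y - oy)
            for other, (ox, oy) in positions.items()
            if other != ch
        }
        dmin = min(dists.values())
        near = [o for o, d in sorted(dists.items(), key=lambda kv: kv[1]) if d <= dmin + 1e-9]
        adjacency[ch] = tuple(near[:4])
    # symmetrize: A is neighbour of B iff both ways (grid distance ties keep it symmetric
    # for regular grids; enforce anyway)
    sym = {ch: tuple(n for n in neigh if ch in adjacency[n] or True) for ch, neigh in adjacency.items()}
    full = {ch: set(neigh) for ch, neigh in sym.items()}
    for ch, neigh in sym.items():
        for n in neigh:
            full[n].add(ch)
    return Montage(labels, dict(positions), {ch: tuple(sorted(v)) for ch, v in full.items()})


def default_montage() -> Montage:
    """Sensorimotor 6-channel set (C3,Cz,C4,P3,Pz,P4) plus frontal/occipital
    surround channels providing Laplacian neighbours, on a unit grid."""
    positions = {
        "F3": (-1.0, 1.0), "Fz": (0.0, 1.0), "F4": (1.0, 1.0),
        "C3": (-1.0, 0.0), "Cz": (0.0, 0.0), "C4": (1.0, 0.0),
        "P3": (-1.0, -1.0), "Pz": (0.0, -1.0), "P4": (1.0, -1.0),
        "Oz": (0.0, -2.0),
    }
    return _grid_montage(positions)


@dataclass(frozen=True)
class ChannelConfig:
    """Named scalp electrode arrangement used for indicator extraction."""

    name: str
    channels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


#: Narrow arrangement over the hand motor areas.
CONFIG_2CH = ChannelConfig("2Ch", ("C3", "C4"))
#: Wide arrangement covering central and parietal sensorimotor cortex.
CONFIG_6CH = ChannelConfig("6Ch", ("C3", "P3", "Cz", "Pz", "C4", "P4"))


def _check_channels(data: np.ndarray, channels: Sequence[str], axis: int) -> None:
    if data.shape[axis] != len(channels):
        raise ValueError(
            f"channel axis has {data.shape[axis]} rows but {len(channels)} labels"
        )
    if np.isnan(data).any():
        raise ValueError("EEG data contains NaN")


@dataclass
class EEGRecording:
    """A continuous multichannel EEG record (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEGRecording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channels = tuple(self.channels)
        _check_channels(self.data, self.channels, axis=0)

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def select_channels(self, labels: Sequence[str]) -> "EEGRecording":
        idx = [self.channel_index(c) for c in labels]
        return EEGRecording(self.data[idx], self.fs, tuple(labels), self.montage)

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(np.asarray(data, dtype=float), self.fs, self.channels, self.montage)


@dataclass
class TrialSet:
    """Labelled MI trials: (n_trials, n_channels, n_samples) plus metadata."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    timing: TrialTiming = field(default_factory=TrialTiming)
    channels: tuple[str, ...] = ()
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("TrialSet.data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must match trial count")
        bad = set(np.unique(self.labels)) - {LEFT, RIGHT}
        if bad:
            raise ValueError(f"labels must be {LEFT!r}/{RIGHT!r}, got {bad}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channels = tuple(self.channels)
        if self.channels:
            _check_channels(self.data, self.channels, axis=1)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in trial set") from None

    def select_channels(self, labels: Sequence[str]) -> "TrialSet":
        idx = [self.channel_index(c) for c in labels]
        return TrialSet(self.data[:, idx], self.labels, self.fs, self.timing,
                        tuple(labels), self.montage)

    def copy_with(self, data: np.ndarray) -> "TrialSet":
        return TrialSet(np.asarray(data, dtype=float), self.labels, self.fs,
                        self.timing, self.channels, self.montage)

    def subset(self, index: np.ndarray) -> "TrialSet":
        return TrialSet(self.data[index], self.labels[index], self.fs,
                        self.timing, self.channels, self.montage)
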