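"""Pre-processing: band-pass filtering, surface Laplacian, segmentation.

Conventions: zero-phase (forward-backward) 4th-order Butterworth filters;
half-open time intervals ``[t0, t1)`` with time 0 at trial onset and
0-based sample indexing.
"""

from __future__ import annotations

import logging
from typing import Sequence, Union

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, Montage, TrialSet

__all__ = ["bandpass", "laplacian", "segment", "trim_resting",
           "BROAD_BAND", "MU_BAND", "BETA_BAND"]

logger = logging.getLogger(__name__)

#: Analysis bands (Hz): broadband for classification, mu/beta for ERD/ERS.
BROAD_BAND = (4.0, 40.0)
MU_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 30.0)

Signals = Union[EEGRecording, TrialSet]


def _apply_channelwise(obj: Signals, fn) -> Signals:
    return obj.copy_with(fn(obj.data))


def bandpass(obj: Signals, low: float = BROAD_BAND[0], high: float = BROAD_BAND[1],
             order: int = 4) -> Signals:
    """Zero-phase Butterworth band-pass applied channel-wise.

    Default band 4–40 Hz covers both sensorimotor rhythms; pass
    ``MU_BAND`` or ``BETA_BAND`` for the sub-band filters.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= obj.fs / 2:
        raise ValueError("high edge must be below the Nyquist frequency")
    sos = sps.butter(order, [low, high], btype="band", fs=obj.fs, output="sos")
    return _apply_channelwise(obj, lambda d: sps.sosfiltfilt(sos, d, axis=-1))


def laplacian(obj: Signals, montage: Montage | None = None) -> Signals:
    """Small surface Laplacian: subtract the mean of grid neighbours.

    Channels with fewer than 2 neighbours in the adjacency are passed
    through unchanged with a logged warning.
    """
    montage = montage or obj.montage
    if montage is None:
        raise ValueError("no montage available for Laplacian filtering")
    for ch in obj.channels:
        if ch not in montage.labels:
            raise KeyError(f"montage is missing channel {ch!r}")
    out = obj.data.copy()
    ch_index = {c: i for i, c in enumerate(obj.channels)}
    for ch in obj.channels:
        neigh = [n for n in montage.neighbors(ch) if n in ch_index]
        if len(neigh) < 2:
            logger.warning("channel %s has %d neighbours; passed through", ch, len(neigh))
            continue
        idx = [ch_index[n] for n in neigh]
        out[..., ch_index[ch], :] = obj.data[..., ch_index[ch], :] - obj.data[..., idx, :].mean(axis=-2)
    return obj.copy_with(out)


def segment(trials: TrialSet, interval: str | Sequence[float]) -> TrialSet:
    """Crop every trial to a half-open time interval ``[t0, t1)``.

    ``interval`` is either a named interval (``"baseline"`` for the
    pre-cue fixation window, ``"mi"`` for the motor-imagery window) or
    an explicit ``(t0, t1)`` pair in seconds from trial onset.
    """
    if isinstance(interval, str):
        t0, t1 = trials.timing.interval(interval)
    else:
        t0, t1 = interval
    if not t1 > t0:
        raise ValueError("empty interval")
    if t0 < 0 or t1 > trials.timing.trial_length_s + 1e-9:
        raise ValueError("interval outside the trial")
    i0 = int(round(t0 * trials.fs))
    n = int(round((t1 - t0) * trials.fs))
    if i0 + n > trials.n_samples:
        raise ValueError("interval exceeds the available samples")
    cropped = trials.copy_with(trials.data[:, :, i0:i0 + n])
    return cropped


def trim_resting(rec: EEGRecording, drop_s: float = 5.0) -> EEGRecording:
    """Remove the first ``drop_s`` seconds of a resting record.

    The conventional 60 s resting record yields a 55 s analysis segment.
    """
    if drop_s < 0:
        raise ValueError("drop_s must be nonnegative")
    if rec.duration_s <= drop_s:
        raise ValueError("record shorter than the trim length")
    i0 = int(round(drop_s * rec.fs))
    return rec.copy_with(rec.data[:, i0:])
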