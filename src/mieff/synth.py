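"""Synthetic motor-imagery EEG cohorts with known latent efficiency.

Each simulated subject carries a latent ``efficiency`` in [0, 1] that
controls both the prominence of the sensorimotor mu/beta spectral peaks
and the depth of the event-related desynchronization (ERD) during the
motor-imagery interval.  Trials are built as 1/f-shaped Gaussian
background noise (power spectrum ``k1 + k2 / f**eta``) plus band-limited
mu and beta oscillations over the sensorimotor electrodes; during the MI
interval the oscillation amplitude on the channel contralateral to the
imagined hand is attenuated by ``sqrt(1 - erd_depth)`` with 100 ms
cosine ramps, so the band power drops by the factor ``1 - erd_depth``.

Everything is deterministic given the profile seed, which makes the
generator usable as ground truth for parameter-recovery tests of every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import (
    LEFT,
    RIGHT,
    EEGRecording,
    Montage,
    TrialSet,
    TrialTiming,
    default_montage,
)

__all__ = [
    "SubjectProfile",
    "make_cohort",
    "simulate_trial_set",
    "simulate_resting",
    "true_response",
    "make_regression_cohort",
    "RegressionCohort",
    "MU_BAND",
    "BETA_BAND",
]

#: Sensorimotor rhythm bands (Hz).
MU_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 30.0)

#: Maximal fractional mu/beta power suppression reached at efficiency 1.
_MAX_ERD_DEPTH = 0.8

#: Relative oscillation amplitude per sensorimotor channel (C3/C4 carry the
#: lateralized rhythm; midline and parietal sites get attenuated copies).
_OSC_CHANNEL_GAIN = {"C3": 1.0, "C4": 1.0, "Cz": 0.5, "Pz": 0.4, "P3": 0.6, "P4": 0.6}


@dataclass(frozen=True)
class SubjectProfile:
    """Generating parameters for one synthetic subject."""

    subject_id: int
    efficiency: float
    mu_peak_hz: float
    beta_peak_hz: float
    mu_amp: float
    beta_amp: float
    noise_k1: float
    noise_k2: float
    noise_eta: float
    erd_depth: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if not 8.0 <= self.mu_peak_hz <= 13.0:
            raise ValueError("mu peak must lie in the mu band [8, 13] Hz")
        if not 14.0 <= self.beta_peak_hz <= 30.0:
            raise ValueError("beta peak must lie in the beta band [14, 30] Hz")


def _erd_depth_of(efficiency: float) -> float:
    """Monotone map latent efficiency -> ERD depth (the generator contract)."""
    return _MAX_ERD_DEPTH * efficiency


def _mu_amp_of(efficiency: float) -> float:
    """Monotone map latent efficiency -> mu oscillation RMS amplitude."""
    return 1.0 + 5.0 * efficiency


def make_cohort(
    n_subjects: int,
    seed: int,
    efficiency_spec: str | float | Sequence[float] = "uniform",
) -> list[SubjectProfile]:
    """Draw a reproducible cohort of subject profiles.

    Parameters
    ----------
    n_subjects : int
        Cohort size (>= 1).
    seed : int
        Master seed; per-subject seeds are spawned from it.
    efficiency_spec : "uniform" | float | sequence of float
        Either the string ``"uniform"`` (efficiencies ~ U(0, 1)), a single
        constant applied to every subject, or an explicit sequence of
        length ``n_subjects``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(efficiency_spec, str):
        if efficiency_spec != "uniform":
            raise ValueError(f"unknown efficiency spec {efficiency_spec!r}")
        eff = rng.uniform(0.0, 1.0, size=n_subjects)
    elif np.isscalar(efficiency_spec):
        eff = np.full(n_subjects, float(efficiency_spec))
    else:
        eff = np.asarray(efficiency_spec, dtype=float)
        if eff.shape != (n_subjects,):
            raise ValueError("explicit efficiency sequence must have length n_subjects")
    if ((eff < 0) | (eff > 1)).any():
        raise ValueError("efficiencies must lie in [0, 1]")

    profiles = []
    for m, e in enumerate(eff):
        profiles.append(
            SubjectProfile(
                subject_id=m,
                efficiency=float(e),
                mu_peak_hz=float(rng.uniform(9.0, 12.0)),
                beta_peak_hz=float(rng.uniform(18.0, 24.0)),
                mu_amp=_mu_amp_of(float(e)),
                beta_amp=0.4 * _mu_amp_of(float(e)),
                noise_k1=float(rng.uniform(0.05, 0.15)),
                noise_k2=float(rng.uniform(3.0, 6.0)),
                noise_eta=float(rng.uniform(0.8, 1.2)),
                erd_depth=_erd_depth_of(float(e)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      k1: float, k2: float, eta: float, n_channels: int) -> np.ndarray:
    """Gaussian noise with one-sided PSD ~ k1 + k2 / f**eta (f in Hz)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    f_safe = np.maximum(freqs, 0.5)          # flatten below 0.5 Hz to avoid DC blow-up
    psd = k1 + k2 / f_safe**eta
    scale = np.sqrt(psd * fs * n / 2.0)
    z = rng.normal(size=(n_channels, freqs.size)) + 1j * rng.normal(size=(n_channels, freqs.size))
    z *= scale / np.sqrt(2.0)
    z[:, 0] = 0.0                            # zero-mean record
    return np.fft.irfft(z, n=n, axis=1)


def _band_oscillation(rng: np.random.Generator, n: int, fs: float,
                      center_hz: float, half_width_hz: float, rms: float) -> np.ndarray:
    """Band-limited oscillation: 4th-order band-passed white noise at unit RMS."""
    lo = max(center_hz - half_width_hz, 0.5)
    hi = min(center_hz + half_width_hz, 0.99 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.normal(size=n))
    sd = x.std()
    if sd > 0:
        x = x / sd
    return rms * x


def _erd_envelope(n: int, fs: float, timing: TrialTiming, depth: float,
                  ramp_s: float = 0.1) -> np.ndarray:
    """Amplitude envelope: 1 outside MI, sqrt(1-depth) inside, cosine ramps."""
    t = np.arange(n) / fs
    m0, m1 = timing.mi_interval_s
    lo = np.sqrt(max(1.0 - depth, 0.0))
    env = np.ones(n)
    core = (t >= m0 + ramp_s) & (t < m1 - ramp_s)
    env[core] = lo
    down = (t >= m0) & (t < m0 + ramp_s)
    env[down] = 1.0 + (lo - 1.0) * 0.5 * (1 - np.cos(np.pi * (t[down] - m0) / ramp_s))
    up = (t >= m1 - ramp_s) & (t < m1)
    env[up] = lo + (1.0 - lo) * 0.5 * (1 - np.cos(np.pi * (t[up] - (m1 - ramp_s)) / ramp_s))
    return env


def _synth_channels(rng: np.random.Generator, profile: SubjectProfile, n: int,
                    fs: float, montage: Montage,
                    erd_channel: str | None, timing: TrialTiming | None) -> np.ndarray:
    """One trial (or resting stretch): noise + oscillations, optional ERD."""
    data = _one_over_f_noise(rng, n, fs, profile.noise_k1, profile.noise_k2,
                             profile.noise_eta, len(montage.labels))
    for ci, ch in enumerate(montage.labels):
        gain = _OSC_CHANNEL_GAIN.get(ch, 0.0)
        if gain == 0.0:
            continue
        mu = _band_oscillation(rng, n, fs, profile.mu_peak_hz, 1.5, gain * profile.mu_amp)
        beta = _band_oscillation(rng, n, fs, profile.beta_peak_hz, 3.0, gain * profile.beta_amp)
        osc = mu + beta
        if erd_channel is not None and ch == erd_channel and timing is not None:
            osc = osc * _erd_envelope(n, fs, timing, profile.erd_depth)
        data[ci] += osc
    return data


def simulate_trial_set(
    profile: SubjectProfile,
    n_trials: int = 50,
    fs: float = 160.0,
    timing: TrialTiming | None = None,
    montage: Montage | None = None,
) -> TrialSet:
    """Simulate a labelled, class-balanced MI trial set for one subject.

    ``n_trials`` is the count per class.  The channel contralateral to the
    imagined hand (C3 for right, C4 for left) expresses the subject's ERD
    during the MI interval.
    """
    timing = timing or TrialTiming()
    montage = montage or default_montage()
    if n_trials < 2:
        raise ValueError("need at least 2 trials per class")
    if fs < 128:
        raise ValueError("sampling rate must be >= 128 Hz")
    if fs < 2 * BETA_BAND[1]:
        raise ValueError("sampling rate below twice the beta band upper edge")
    rng = np.random.default_rng(profile.seed)
    n = int(round(timing.trial_length_s * fs))
    labels = np.array([LEFT, RIGHT] * n_trials)
    rng.shuffle(labels)
    contralateral = {LEFT: "C4", RIGHT: "C3"}
    trials = np.empty((labels.size, len(montage.labels), n))
    for i, lab in enumerate(labels):
        trials[i] = _synth_channels(rng, profile, n, fs, montage,
                                    contralateral[lab], timing)
    return TrialSet(trials, labels, fs, timing, montage.labels, montage)


def simulate_resting(
    profile: SubjectProfile,
    fs: float = 160.0,
    duration_s: float = 60.0,
    montage: Montage | None = None,
) -> EEGRecording:
    """Simulate a single resting-state record (no ERD), default 60 s."""
    montage = montage or default_montage()
    if duration_s < 10:
        raise ValueError("resting duration must be >= 10 s")
    if fs < 2 * BETA_BAND[1]:
        raise ValueError("sampling rate below twice the beta band upper edge")
    rng = np.random.default_rng(profile.seed + 1)
    n = int(round(duration_s * fs))
    data = _synth_channels(rng, profile, n, fs, montage, None, None)
    return EEGRecording(data, fs, montage.labels, montage)


def true_response(profile: SubjectProfile) -> float:
    """Ground-truth expected bi-class accuracy for a profile.

    Linear map of latent efficiency onto [0.5, 0.95]; used by
    parameter-recovery tests, never by the estimators themselves.
    """
    return 0.5 + 0.45 * profile.efficiency


# ---------------------------------------------------------------------------
# Nonlinear-monotone regression cohort
# ---------------------------------------------------------------------------

@dataclass
class RegressionCohort:
    """A cohort for studying indicator-to-response regression.

    ``signals`` holds per-subject, per-channel raw time series whose
    second-order statistics encode the latent efficiency; ``responses``
    is a strongly nonlinear (sigmoidal) but monotone function of the
    latent; ``scalar_indicators`` is the latent passed through a
    saturating transform plus observation noise — the regime in which a
    rank correlation on the scalar stalls while a feature-rich regressor
    can still linearize the relationship.
    """

    latents: np.ndarray            # (M,) latent efficiency in [0, 1]
    responses: np.ndarray          # (M,) sigmoidal response
    scalar_indicators: np.ndarray  # (M,) noisy saturated scalar
    signals: np.ndarray            # (M, C, n_samples) raw per-channel series
    fs: float


def make_regression_cohort(
    n_subjects: int = 50,
    seed: int = 0,
    n_channels: int = 2,
    duration_s: float = 6.0,
    fs: float = 256.0,
    noise_sd: float = 0.25,
    saturation: float = 8.0,
) -> RegressionCohort:
    """Generate the nonlinear-monotone cohort used for regression studies.

    The response is ``sigmoid((t - 0.5) / 0.12)`` of the latent ``t``;
    the scalar indicator is ``tanh(saturation * t) + N(0, noise_sd)``;
    per-channel signals are white noise with standard deviation
    ``0.5 + t`` so that windowed moment features carry many independent
    noisy views of the latent.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_subjects)
    responses = 1.0 / (1.0 + np.exp(-(t - 0.5) / 0.12))
    scalar = np.tanh(saturation * t) + rng.normal(0.0, noise_sd, size=n_subjects)
    n = int(round(duration_s * fs))
    signals = rng.normal(size=(n_subjects, n_channels, n)) * (0.5 + t)[:, None, None]
    return RegressionCohort(t, responses, scalar, signals, fs)
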