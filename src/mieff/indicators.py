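"""Neurophysiological indicators of motor-imagery ability.

Two indicators are computed per subject:

* the **pre-training desynchronization indicator** ``xi1`` — the maximal
  excess of the resting power spectral density over its fitted
  1/f-type background.  The PSD over 4–40 Hz is modelled as two
  Gaussian peaks (mu and beta rhythms) on a hyperbolic noise floor::

      s(f) ~ k_mu G(f; m_mu, s_mu) + k_beta G(f; m_beta, s_beta)
             + kappa1 + kappa2 / f**eta

  with ``G`` an unnormalized Gaussian bump, fitted by bounded nonlinear
  least squares; ``xi1 = mean_c max_f ( s_c(f) - noise_c(f) )`` over the
  channel configuration, floored at zero per channel.

* the **initial-training synchronization indicator** ``xi2`` — the
  normalized squared distance between the left- and right-hand
  ERD/ERS time courses, maximized over rhythm bands and channels::

      xi2 = max_{band, c}  ||z_l - z_r||^2 / ( ||z_l|| * ||z_r|| )

  where ``z`` is the relative band-power time course
  ``(power(t) - ref) / ref`` over the motor-imagery interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal as sps, stats

from .containers import LEFT, RIGHT, ChannelConfig, EEGRecording, TrialSet
from .preprocess import BETA_BAND, MU_BAND, bandpass, segment, trim_resting

__all__ = [
    "PSDEstimate",
    "PSDFitModel",
    "ERDSTimeCourse",
    "welch_psd",
    "fit_psd_model",
    "xi1",
    "compute_xi1",
    "erds",
    "pair_distance",
    "xi2",
    "compute_xi2",
    "run_trend_test",
    "RunTrendResult",
    "BAND_MAP",
]

logger = logging.getLogger(__name__)

#: Named rhythm bands.
BAND_MAP = {"mu": MU_BAND, "beta": BETA_BAND}

#: Fitting range (Hz) of the spectral model.
FIT_RANGE = (4.0, 40.0)


# ---------------------------------------------------------------------------
# PSD estimation and spectral-model fitting
# ---------------------------------------------------------------------------

@dataclass
class PSDEstimate:
    """Welch power spectral density of one channel."""

    frequencies: np.ndarray
    power: np.ndarray
    channel: str = ""
    win_s: float = 1.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency grid and power must have the same shape")
        if (np.diff(self.frequencies) <= 0).any():
            raise ValueError("frequency grid must be strictly increasing")
        if (self.power < 0).any():
            raise ValueError("PSD must be nonnegative")

    def restrict(self, low: float, high: float) -> "PSDEstimate":
        m = (self.frequencies >= low) & (self.frequencies <= high)
        return PSDEstimate(self.frequencies[m], self.power[m], self.channel,
                           self.win_s, self.overlap)


def welch_psd(x: np.ndarray, fs: float, win_s: float = 1.0, overlap: float = 0.5,
              channel: str = "") -> PSDEstimate:
    """Welch PSD with sliding windows of ``win_s`` seconds and 50% overlap."""
    x = np.asarray(x, dtype=float)
    nper = int(round(win_s * fs))
    if x.size < nper:
        raise ValueError("signal shorter than one Welch window")
    f, p = sps.welch(x, fs=fs, nperseg=nper, noverlap=int(round(nper * overlap)))
    return PSDEstimate(f, p, channel, win_s, overlap)


@dataclass
class PSDFitModel:
    """Fitted two-Gaussian-plus-hyperbolic spectral model for one channel."""

    k_mu: float
    m_mu: float
    s_mu: float
    k_beta: float
    m_beta: float
    s_beta: float
    kappa1: float
    kappa2: float
    eta: float
    residual: float
    converged: bool
    channel: str = ""

    def noise(self, f: np.ndarray) -> np.ndarray:
        """The aperiodic component kappa1 + kappa2 / f**eta."""
        f = np.asarray(f, dtype=float)
        return self.kappa1 + self.kappa2 / np.maximum(f, 1e-6) ** self.eta

    def peaks(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return (_gauss(f, self.k_mu, self.m_mu, self.s_mu)
                + _gauss(f, self.k_beta, self.m_beta, self.s_beta))

    def model(self, f: np.ndarray) -> np.ndarray:
        return self.peaks(f) + self.noise(f)


def _gauss(f: np.ndarray, k: float, m: float, s: float) -> np.ndarray:
    return k * np.exp(-0.5 * ((f - m) / s) ** 2)


def _spectral_model(p: np.ndarray, f: np.ndarray) -> np.ndarray:
    k_mu, m_mu, s_mu, k_beta, m_beta, s_beta, kap1, kap2, eta = p
    return (_gauss(f, k_mu, m_mu, s_mu) + _gauss(f, k_beta, m_beta, s_beta)
            + kap1 + kap2 / f**eta)


_LOWER = np.array([0.0, MU_BAND[0], 0.25, 0.0, BETA_BAND[0], 0.5, 0.0, 0.0, 0.0])
_UPPER = np.array([np.inf, MU_BAND[1], 6.0, np.inf, BETA_BAND[1], 10.0,
                   np.inf, np.inf, 4.0])


def fit_psd_model(psd: PSDEstimate, n_starts: int = 5, seed: int = 0) -> PSDFitModel:
    """Fit the two-peak-plus-noise model by bounded least squares.

    Box constraints keep the peak centres inside their rhythm bands and
    every parameter nonnegative.  ``n_starts`` seeded multistarts are
    run and the lowest-residual solution kept; if no start converges the
    best attempt is returned flagged as non-converged.
    """
    sub = psd.restrict(*FIT_RANGE)
    if sub.frequencies.size < 10:
        raise ValueError("PSD must cover the 4-40 Hz fitting range")
    f, s = sub.frequencies, sub.power
    scale = max(float(s.max()), 1e-12)

    def residuals(p):
        return _spectral_model(p, f) - s

    # heuristic start: floor from the spectrum tail, peaks at band maxima
    tail = float(np.median(s[f > 30])) if (f > 30).any() else float(s.min())
    mu_m = (f >= MU_BAND[0]) & (f <= MU_BAND[1])
    be_m = (f >= BETA_BAND[0]) & (f <= BETA_BAND[1])
    p0 = np.array([
        max(float(s[mu_m].max() - tail), 1e-3) if mu_m.any() else scale / 2,
        float(f[mu_m][np.argmax(s[mu_m])]) if mu_m.any() else 10.0,
        1.5,
        max(float(s[be_m].max() - tail), 1e-3) if be_m.any() else scale / 4,
        float(f[be_m][np.argmax(s[be_m])]) if be_m.any() else 20.0,
        3.0,
        max(tail, 1e-6),
        max(float(s[0] - tail) * f[0], 1e-6),
        1.0,
    ])
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        p_init = p0.copy()
        if start > 0:
            jitter = rng.uniform(0.5, 1.5, size=p0.size)
            p_init = p0 * jitter
            p_init[1] = rng.uniform(*MU_BAND)
            p_init[4] = rng.uniform(*BETA_BAND)
        p_init = np.clip(p_init, _LOWER + 1e-9, np.where(np.isinf(_UPPER), p_init + 1, _UPPER - 1e-9))
        try:
            sol = optimize.least_squares(residuals, p_init, bounds=(_LOWER, _UPPER),
                                         method="trf", max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        res = float(np.linalg.norm(sol.fun))
        if best is None or res < best[0]:
            best = (res, sol.x, bool(sol.success))
    if best is None:
        logger.warning("PSD fit failed on every start for channel %s", psd.channel)
        return PSDFitModel(*p0, residual=float(np.linalg.norm(residuals(p0))),
                           converged=False, channel=psd.channel)
    res, p, ok = best
    if not ok:
        logger.warning("PSD fit did not converge for channel %s", psd.channel)
    return PSDFitModel(*p, residual=res, converged=ok, channel=psd.channel)


def xi1(psds: Sequence[PSDEstimate], fits: Sequence[PSDFitModel]) -> float:
    """Pre-training desynchronization indicator.

    Per channel, the maximal excess of the measured PSD over the fitted
    noise floor (floored at 0); averaged over the channel configuration.
    """
    if len(psds) != len(fits):
        raise ValueError("need one fit per PSD")
    ref = psds[0].restrict(*FIT_RANGE).frequencies
    values = []
    for psd, fit in zip(psds, fits):
        sub = psd.restrict(*FIT_RANGE)
        if sub.frequencies.shape != ref.shape or not np.allclose(sub.frequencies, ref):
            raise ValueError("PSD frequency grids differ between channels")
        excess = sub.power - fit.noise(sub.frequencies)
        values.append(max(float(excess.max()), 0.0))
    return float(np.mean(values))


@dataclass
class Xi1Result:
    """xi1 with its per-channel breakdown and fitted spectral models."""

    value: float
    per_channel: dict[str, float]
    fits: list[PSDFitModel]
    psds: list[PSDEstimate]


def compute_xi1(data: TrialSet | EEGRecording, config: ChannelConfig,
                scenario: str = "resting", win_s: float = 1.0,
                seed: int = 0) -> Xi1Result:
    """End-to-end xi1 for one subject.

    ``scenario="baseline"`` concatenates the pre-cue baseline segments of
    all trials per channel; ``scenario="resting"`` uses the (trimmed)
    resting record.  The input is expected to be Laplacian-filtered.
    """
    if scenario == "baseline":
        if not isinstance(data, TrialSet):
            raise TypeError("baseline scenario needs a TrialSet")
        seg = segment(data.select_channels(config.channels), "baseline")
        per_channel = {c: seg.data[:, i, :].reshape(-1)
                       for i, c in enumerate(config.channels)}
        fs = seg.fs
    elif scenario == "resting":
        if not isinstance(data, EEGRecording):
            raise TypeError("resting scenario needs an EEGRecording")
        rec = trim_resting(data) if data.duration_s > 55 else data
        rec = rec.select_channels(config.channels)
        per_channel = {c: rec.data[i] for i, c in enumerate(config.channels)}
        fs = rec.fs
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    psds, fits, per_ch = [], [], {}
    for c, x in per_channel.items():
        psd = welch_psd(x, fs, win_s=win_s, channel=c)
        fit = fit_psd_model(psd, seed=seed)
        sub = psd.restrict(*FIT_RANGE)
        per_ch[c] = max(float((sub.power - fit.noise(sub.frequencies)).max()), 0.0)
        psds.append(psd)
        fits.append(fit)
    return Xi1Result(float(np.mean(list(per_ch.values()))), per_ch, fits, psds)


# ---------------------------------------------------------------------------
# ERD/ERS time courses and xi2
# ---------------------------------------------------------------------------

@dataclass
class ERDSTimeCourse:
    """Relative band-power time course for one (band, channel, class)."""

    times: np.ndarray          # seconds from trial onset
    zhat: np.ndarray           # (power - ref) / ref, per sample
    zhat_masked: np.ndarray    # zhat with non-significant samples zeroed
    power: np.ndarray          # trial-averaged instantaneous power
    ref_mean: float            # reference-interval mean power
    band: str = ""
    channel: str = ""
    label: str = ""
    ref_interval: tuple[float, float] = (0.5, 1.5)

    def crop(self, t0: float, t1: float, masked: bool = True) -> np.ndarray:
        m = (self.times >= t0) & (self.times < t1)
        return (self.zhat_masked if masked else self.zhat)[m]


def erds(trials: TrialSet, band: str, channel: str,
         ref_interval: tuple[float, float] = (0.5, 1.5),
         alpha: float = 0.01, prefiltered: bool = False) -> dict[str, ERDSTimeCourse]:
    """ERD/ERS time course per class for one rhythm band and channel.

    The per-sample power is the squared band-filtered signal averaged
    over that class's trials; the curve is expressed relative to its
    mean over the reference interval.  Samples whose z-score against the
    reference-interval distribution is non-significant (two-sided, level
    ``alpha``) are masked to 0.
    """
    if band not in BAND_MAP:
        raise KeyError(f"unknown band {band!r}; expected one of {sorted(BAND_MAP)}")
    one = trials.select_channels([channel])
    if not prefiltered:
        one = bandpass(one, *BAND_MAP[band])
    t = np.arange(one.n_samples) / one.fs
    r0, r1 = ref_interval
    b0, b1 = trials.timing.fixation_s
    if not (b0 <= r0 < r1 <= b1):
        raise ValueError("reference interval must lie inside the baseline")
    ref_mask = (t >= r0) & (t < r1)
    out: dict[str, ERDSTimeCourse] = {}
    zcrit = stats.norm.ppf(1 - alpha / 2)
    for label in (LEFT, RIGHT):
        sel = one.class_mask(label)
        if sel.sum() < 2:
            raise ValueError(f"need at least 2 trials of class {label!r}")
        power = (one.data[sel, 0, :] ** 2).mean(axis=0)
        ref = float(power[ref_mask].mean())
        if ref <= 0:
            raise ValueError("degenerate (zero) reference power")
        if power.var() <= power[ref_mask].var():
            warnings.warn(
                f"power variance over the trial does not dominate the reference "
                f"variance for ({band},{channel},{label}); ERD/ERS may be unreliable",
                stacklevel=2)
        zhat = (power - ref) / ref
        mu_ref = float(zhat[ref_mask].mean())
        sd_ref = float(zhat[ref_mask].std())
        if sd_ref == 0:
            mask = np.zeros_like(zhat, dtype=bool)
        else:
            mask = np.abs((zhat - mu_ref) / sd_ref) >= zcrit
        out[label] = ERDSTimeCourse(t, zhat, np.where(mask, zhat, 0.0), power,
                                    ref, band, channel, label, (r0, r1))
    return out


def pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized squared distance ||a-b||^2 / (||a|| ||b||) between curves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("class curves must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("zero-norm curve")
    return float(np.sum((a - b) ** 2) / (na * nb))


def xi2(erds_by_pair: Mapping[tuple[str, str], Mapping[str, np.ndarray]]) -> float:
    """Initial-training synchronization indicator from MI-interval curves.

    ``erds_by_pair`` maps (band, channel) to the two class curves (already
    restricted to the MI interval).  Pairs with a zero-norm curve are
    skipped with a warning; if every pair degenerates, 0 is returned.
    """
    values = []
    for (band, ch), curves in erds_by_pair.items():
        try:
            values.append(pair_distance(curves[LEFT], curves[RIGHT]))
        except ZeroDivisionError:
            warnings.warn(f"zero-norm ERD/ERS curve for ({band},{ch}); pair skipped",
                          stacklevel=2)
    if not values:
        return 0.0
    return float(max(values))


@dataclass
class Xi2Result:
    value: float
    per_pair: dict[tuple[str, str], float]
    curves: dict[tuple[str, str], dict[str, ERDSTimeCourse]]


def compute_xi2(trials: TrialSet, config: ChannelConfig,
                bands: Sequence[str] = ("mu", "beta"),
                ref_interval: tuple[float, float] = (0.5, 1.5),
                alpha: float = 0.01, masked: bool = True) -> Xi2Result:
    """End-to-end xi2: ERD/ERS per (band, channel), distance on the MI interval,
    maximum over all pairs.  For multi-band requests the maximization ranges
    over every (band, channel) pair rather than a summed band signal."""
    m0, m1 = trials.timing.mi_interval_s
    per_pair: dict[tuple[str, str], float] = {}
    curves: dict[tuple[str, str], dict[str, ERDSTimeCourse]] = {}
    cropped: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for band in bands:
        for ch in config.channels:
            tc = erds(trials, band, ch, ref_interval, alpha)
            curves[(band, ch)] = tc
            cropped[(band, ch)] = {lab: c.crop(m0, m1, masked=masked)
                                   for lab, c in tc.items()}
            try:
                per_pair[(band, ch)] = pair_distance(cropped[(band, ch)][LEFT],
                                                     cropped[(band, ch)][RIGHT])
            except ZeroDivisionError:
                pass
    return Xi2Result(xi2(cropped), per_pair, curves)


# ---------------------------------------------------------------------------
# Run-wise xi2 trend
# ---------------------------------------------------------------------------

@dataclass
class RunTrendResult:
    """Per-run xi2 values across a cohort with consecutive-run paired tests."""

    xi2_per_run: np.ndarray     # (n_subjects, n_runs)
    run_means: np.ndarray       # (n_runs,)
    p_values: np.ndarray        # (n_runs - 1,) Wilcoxon, consecutive pairs
    alpha: float
    run_size: int


def run_trend_test(cohort: Sequence[TrialSet], run_size: int = 30,
                   alpha: float = 0.05, bands: Sequence[str] = ("mu", "beta"),
                   config: ChannelConfig | None = None,
                   max_runs: int = 3) -> RunTrendResult:
    """xi2 per consecutive run of ``run_size`` time-ordered trials, with a
    paired Wilcoxon signed-rank test between consecutive runs across subjects.

    At most ``max_runs`` complete runs per subject are used (trial counts
    differ between subjects); every subject must supply at least two.
    """
    from .containers import CONFIG_2CH
    config = config or CONFIG_2CH
    n_runs = min(min(ts.n_trials // run_size for ts in cohort), max_runs)
    if n_runs < 2:
        raise ValueError("need at least 2 complete runs per subject")
    values = np.empty((len(cohort), n_runs))
    for m, ts in enumerate(cohort):
        for r in range(n_runs):
            run = ts.subset(np.arange(r * run_size, (r + 1) * run_size))
            values[m, r] = compute_xi2(run, config, bands, alpha=alpha).value
    pvals = np.empty(n_runs - 1)
    for r in range(n_runs - 1):
        d = values[:, r] - values[:, r + 1]
        if np.allclose(d, 0):
            pvals[r] = 1.0
        else:
            pvals[r] = stats.wilcoxon(values[:, r], values[:, r + 1]).pvalue
    return RunTrendResult(values, values.mean(axis=0), pvals, alpha, run_size)
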