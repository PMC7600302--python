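"""Bi-class accuracy response: sliding-window CSP features + regularized LDA.

The per-subject response is the cross-validated accuracy of a Common
Spatial Patterns + Linear Discriminant Analysis classifier, computed on
windows of length ``delta_tau`` in {0.5, 1.0, 1.5, 2.0} s slid with 50%
overlap across the motor-imagery interval.  The per-``delta_tau``
summary is the maximum mean CV accuracy over window positions (the mean
over positions is kept alongside for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .containers import LEFT, RIGHT, ChannelConfig, TrialSet
from .preprocess import BROAD_BAND, bandpass, segment

__all__ = ["CSPModel", "fit_csp", "csp_features", "AccuracyResponse",
           "accuracy_response", "DELTA_TAUS"]

#: Feature-extraction window lengths (s).
DELTA_TAUS = (0.5, 1.0, 1.5, 2.0)


# ---------------------------------------------------------------------------
# Common Spatial Patterns
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """Spatial filters jointly diagonalizing the two class covariances."""

    filters: np.ndarray        # (n_filters, n_channels)
    eigenvalues: np.ndarray    # generalized eigenvalues of the selected filters
    n_per_class: int
    shrinkage: float


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance per trial, (n, C, C)."""
    cov = np.einsum("ict,idt->icd", data, data) / data.shape[2]
    tr = np.trace(cov, axis1=1, axis2=2)
    return cov / np.maximum(tr, 1e-30)[:, None, None]


def _class_covariance(covs: np.ndarray, shrinkage: float) -> np.ndarray:
    mean = covs.mean(axis=0)
    c = mean.shape[0]
    return (1 - shrinkage) * mean + shrinkage * (np.trace(mean) / c) * np.eye(c)


def fit_csp(trials: TrialSet, n_per_class: int = 3, shrinkage: float = 0.05) -> CSPModel:
    """Fit CSP filters on one window of band-filtered trials.

    Per-trial covariances are trace-normalized, averaged per class and
    shrunk toward a scaled identity; the generalized eigendecomposition
    of ``(Sigma_l, Sigma_l + Sigma_r)`` yields the filters.  Up to
    ``n_per_class`` eigenvectors are kept from each end of the spectrum
    (limited by ``n_channels // 2`` when the montage is small).
    """
    for lab in (LEFT, RIGHT):
        if trials.class_mask(lab).sum() < 2:
            raise ValueError(f"need at least 2 trials of class {lab!r}")
    covs = _trial_covariances(trials.data)
    sig_l = _class_covariance(covs[trials.class_mask(LEFT)], shrinkage)
    sig_r = _class_covariance(covs[trials.class_mask(RIGHT)], shrinkage)
    composite = sig_l + sig_r
    try:
        w, v = linalg.eigh(sig_l, composite)
    except linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError("singular composite covariance after shrinkage") from err
    k = min(n_per_class, trials.n_channels // 2)
    if k < 1:
        raise ValueError("need at least 2 channels for CSP")
    order = np.argsort(w)
    sel = np.concatenate([order[-k:][::-1], order[:k]])
    return CSPModel(v[:, sel].T, w[sel], k, shrinkage)


def csp_features(trials: TrialSet, csp: CSPModel) -> np.ndarray:
    """Normalized log-variance of the CSP projections, (n_trials, 2k)."""
    proj = np.einsum("fc,ict->ift", csp.filters, trials.data)
    var = proj.var(axis=2)
    if (var <= 0).any():
        raise ValueError("zero-variance CSP projection")
    return np.log(var / var.sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Sliding-window accuracy response
# ---------------------------------------------------------------------------

@dataclass
class AccuracyResponse:
    """Per-subject accuracy across feature-extraction window lengths."""

    delta_taus: tuple[float, ...]
    max_accuracy: dict[float, float]         # summary: max over window positions
    mean_accuracy: dict[float, float]        # sensitivity: mean over positions
    curves: dict[float, np.ndarray]          # accuracy per window position
    window_starts: dict[float, np.ndarray]   # seconds from trial onset
    dispersion: dict[float, float]           # CV std at the maximizing window

    @property
    def v_m(self) -> np.ndarray:
        """The response vector: summary accuracy at each delta_tau."""
        return np.array([self.max_accuracy[dt] for dt in self.delta_taus])

    def to_frame(self, subject: int | str = 0) -> pd.DataFrame:
        rows = [
            {"subject": subject, "delta_tau": dt,
             "accuracy": self.max_accuracy[dt],
             "mean_accuracy": self.mean_accuracy[dt],
             "dispersion": self.dispersion[dt]}
            for dt in self.delta_taus
        ]
        return pd.DataFrame(rows)


def _cv_accuracy(covs: np.ndarray, y: np.ndarray, n_splits: int, n_repeats: int,
                 seed: int, n_per_class: int, shrinkage: float) -> tuple[float, float]:
    """Stratified repeated K-fold CSP+LDA accuracy from per-trial covariances."""
    accs = []
    c = covs.shape[1]
    k = min(n_per_class, c // 2)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(np.zeros(len(y)), y):
            sig_l = _class_covariance(covs[train][y[train] == LEFT], shrinkage)
            sig_r = _class_covariance(covs[train][y[train] == RIGHT], shrinkage)
            w, v = linalg.eigh(sig_l, sig_l + sig_r)
            order = np.argsort(w)
            filt = v[:, np.concatenate([order[-k:][::-1], order[:k]])].T
            var = np.einsum("fc,icd,gd->ifg", filt, covs, filt)
            var = np.maximum(np.diagonal(var, axis1=1, axis2=2), 1e-30)
            feats = np.log(var / var.sum(axis=1, keepdims=True))
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(feats[train], y[train])
            accs.append(lda.score(feats[test], y[test]))
    return float(np.mean(accs)), float(np.std(accs))


def accuracy_response(
    trials: TrialSet,
    config: ChannelConfig,
    delta_taus: Sequence[float] = DELTA_TAUS,
    cv: tuple[int, int] = (10, 10),
    seed: int = 0,
    n_per_class: int = 3,
    shrinkage: float = 0.05,
    prefiltered: bool = False,
) -> AccuracyResponse:
    """Sliding-window CSP/LDA accuracy for one subject.

    ``cv = (repeats, folds)`` controls the repeated stratified
    cross-validation (default 10x10-fold); CSP and LDA are refit inside
    every training fold.  Windows of length ``delta_tau`` are slid with
    50% overlap across the motor-imagery interval.
    """
    if trials.n_trials < 20:
        raise ValueError("need at least 20 trials for a stable accuracy response")
    n_repeats, n_splits = cv
    sel = trials.select_channels(config.channels)
    if not prefiltered:
        sel = bandpass(sel, *BROAD_BAND)
    mi = segment(sel, "mi")
    m0, m1 = trials.timing.mi_interval_s
    mi_len = m1 - m0
    y = mi.labels
    max_acc, mean_acc, curves, starts, disp = {}, {}, {}, {}, {}
    for dt in delta_taus:
        if dt > mi_len + 1e-9:
            raise ValueError(f"delta_tau={dt} exceeds the MI interval length")
        step = dt / 2.0
        n_pos = int(np.floor((mi_len - dt) / step + 1e-9)) + 1
        win = int(round(dt * mi.fs))
        accs = np.empty(n_pos)
        stds = np.empty(n_pos)
        pos_starts = np.empty(n_pos)
        for p in range(n_pos):
            i0 = int(round(p * step * mi.fs))
            covs = _trial_covariances(mi.data[:, :, i0:i0 + win])
            accs[p], stds[p] = _cv_accuracy(covs, y, n_splits, n_repeats,
                                            seed + 1000 * p, n_per_class, shrinkage)
            pos_starts[p] = m0 + p * step
        best = int(np.argmax(accs))
        max_acc[dt] = float(accs[best])
        mean_acc[dt] = float(accs.mean())
        curves[dt] = accs
        starts[dt] = pos_starts
        disp[dt] = float(stds[best])
    return AccuracyResponse(tuple(delta_taus), max_acc, mean_acc, curves, starts, disp)
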