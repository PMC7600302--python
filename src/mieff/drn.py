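"""Wide&Deep regression of BCI performance on indicator features.

The estimator jointly extracts a data-driven subject indicator ``xi*``
and regresses it on the bi-class accuracy response.  Its deep path runs
per-channel moment features through a per-electrode dense branch
(``h = ceil(1.5 d)`` tanh units for feature length ``d``), concatenates
the branches (size ``h * C``), applies a second dense tanh layer of size
``ceil(0.5 h C)`` and a one-neuron linear output; the wide path adds a
direct linear shortcut from the concatenated raw (standardized)
features to the output.  Training minimizes the mean absolute error
with elastic-net weight regularization (l1 = l2 = 1e-3) using Adam at
learning rate 1e-3, full batch.

The module follows the model/results idiom: :class:`DeepRegressionNetwork`
is built from data and ``fit()`` returns a :class:`DRNResults` carrying
the per-subject indicator ``xi*``, diagnostics and a ``summary()``.

A scalar variant (the ablation in which the network is fed a single
precomputed indicator value per subject and the concatenation stage
disappears) is obtained automatically when the features are 1-D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LEFT, RIGHT, ChannelConfig, EEGRecording, TrialSet
from .preprocess import segment, trim_resting

__all__ = [
    "moment_features",
    "SubjectData",
    "build_inputs",
    "DRNArchitecture",
    "build_drn",
    "DeepRegressionNetwork",
    "DRNResults",
    "RegressionResult",
    "psi_map",
    "evaluate",
    "linear_baseline",
    "loo_evaluate",
]


# ---------------------------------------------------------------------------
# Moment features
# ---------------------------------------------------------------------------

def moment_features(x: np.ndarray, fs: float, win_s: float = 1.0,
                    overlap: float = 0.5) -> np.ndarray:
    """Short-time statistical moments of a single-channel signal.

    Per window of length ``win_s`` (50% overlap by default) the mean,
    median, population variance, minimum and maximum are computed;
    windows are concatenated in time order into one feature vector of
    length ``5 * n_windows``.
    """
    x = np.asarray(x, dtype=float).ravel()
    win = int(round(win_s * fs))
    if x.size < win or win < 1:
        raise ValueError("signal shorter than one feature window")
    step = max(int(round(win * (1.0 - overlap))), 1)
    n_win = (x.size - win) // step + 1
    idx = np.arange(win)[None, :] + step * np.arange(n_win)[:, None]
    w = x[idx]
    stats_ = np.column_stack([
        w.mean(axis=1),
        np.median(w, axis=1),
        w.var(axis=1),
        w.min(axis=1),
        w.max(axis=1),
    ])
    return stats_.ravel()


class SubjectData(NamedTuple):
    """Everything the feature builder may need for one subject."""

    trials: TrialSet | None = None
    resting: EEGRecording | None = None


def build_inputs(data: SubjectData, source: str, config: ChannelConfig,
                 bands: Sequence[str] = ("mu", "beta"),
                 win_s: float = 1.0) -> np.ndarray:
    """Per-subject feature stack (C' x d) for the network input.

    Sources:

    * ``"baseline"`` — per channel, the pre-cue baseline segments of all
      trials concatenated in trial order, then moment features;
    * ``"resting"`` — the trimmed resting record per channel;
    * ``"erds"`` — per channel, the two class ERD/ERS curves over the MI
      interval concatenated (left then right, band-major for several
      bands), then moment features.
    """
    from .indicators import erds  # local import avoids a cycle

    if source == "baseline":
        if data.trials is None:
            raise ValueError("baseline source requested but no trials available")
        seg = segment(data.trials.select_channels(config.channels), "baseline")
        rows = [moment_features(seg.data[:, i, :].reshape(-1), seg.fs, win_s)
                for i in range(len(config.channels))]
    elif source == "resting":
        if data.resting is None:
            raise ValueError("resting source requested but no resting record available")
        rec = trim_resting(data.resting) if data.resting.duration_s > 55 else data.resting
        rec = rec.select_channels(config.channels)
        rows = [moment_features(rec.data[i], rec.fs, win_s)
                for i in range(len(config.channels))]
    elif source == "erds":
        if data.trials is None:
            raise ValueError("erds source requested but no trials available")
        m0, m1 = data.trials.timing.mi_interval_s
        rows = []
        for ch in config.channels:
            pieces = []
            for band in bands:
                tc = erds(data.trials, band, ch)
                pieces.append(tc[LEFT].crop(m0, m1, masked=False))
                pieces.append(tc[RIGHT].crop(m0, m1, masked=False))
            rows.append(moment_features(np.concatenate(pieces), data.trials.fs, win_s))
    else:
        raise ValueError(f"unknown source {source!r}")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DRNArchitecture:
    """Layer sizes of the Wide&Deep regressor."""

    d: int                 # per-channel feature length
    n_channels: int        # C'
    scalar_variant: bool

    @property
    def h(self) -> int:
        """Per-channel branch width: ceil(1.5 d)."""
        return math.ceil(1.5 * self.d)

    @property
    def ct_size(self) -> int:
        """Concatenation width h * C' (absent in the scalar variant)."""
        return self.h * self.n_channels

    @property
    def theta2_size(self) -> int:
        """Second dense layer width: ceil(0.5 h C')."""
        return math.ceil(0.5 * self.h * self.n_channels)

    @property
    def theta3_size(self) -> int:
        return 1


def build_drn(d: int, n_channels: int, scalar_variant: bool = False) -> DRNArchitecture:
    """Resolve the layer sizes for a feature length and channel count.

    The scalar variant has a single input of length 1 and no
    concatenation stage (h = 2, theta2 = 1 by the same ceiling rules).
    """
    if scalar_variant:
        d, n_channels = 1, 1
    if d < 1 or n_channels < 1:
        raise ValueError("need d >= 1 and n_channels >= 1")
    return DRNArchitecture(d, n_channels, scalar_variant)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

def _init_params(arch: DRNArchitecture, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform hidden layers; zero output-layer and wide weights.

    Zeroing the output and shortcut weights makes the network start as
    the constant predictor and lets the wide (linear) path fit before
    the deep path's gradients switch on, which curbs memorization by the
    high-capacity deep branches on small cohorts.
    """
    d, c, h, p = arch.d, arch.n_channels, arch.h, arch.theta2_size

    def glorot(*shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return {
        "W1": glorot(c, d, h, fan_in=d, fan_out=h),
        "b1": np.zeros((c, h)),
        "W2": glorot(c * h, p, fan_in=c * h, fan_out=p),
        "b2": np.zeros(p),
        "w3": np.zeros(p),
        "b3": np.zeros(1),
        "wide": np.zeros(c * d),
    }


_WEIGHT_KEYS = ("W1", "W2", "w3", "wide")


def _forward(params: Mapping[str, np.ndarray], X: np.ndarray):
    """X: standardized (M, C, d).  Returns (y, cache)."""
    m = X.shape[0]
    A = np.tanh(np.einsum("mcd,cdh->mch", X, params["W1"]) + params["b1"])
    Z = A.reshape(m, -1)
    U = np.tanh(Z @ params["W2"] + params["b2"])
    Xflat = X.reshape(m, -1)
    y = U @ params["w3"] + params["b3"][0] + Xflat @ params["wide"]
    return y, (X, Xflat, A, Z, U)


def _backward(params, cache, g) -> dict[str, np.ndarray]:
    """g = dLoss/dy, shape (M,)."""
    X, Xflat, A, Z, U = cache
    grads: dict[str, np.ndarray] = {}
    grads["wide"] = Xflat.T @ g
    grads["w3"] = U.T @ g
    grads["b3"] = np.array([g.sum()])
    dU = np.outer(g, params["w3"])
    dpre2 = dU * (1.0 - U**2)
    grads["W2"] = Z.T @ dpre2
    grads["b2"] = dpre2.sum(axis=0)
    dZ = dpre2 @ params["W2"].T
    dA = dZ.reshape(A.shape)
    dpre1 = dA * (1.0 - A**2)
    grads["W1"] = np.einsum("mcd,mch->cdh", X, dpre1)
    grads["b1"] = dpre1.sum(axis=0)
    return grads


class DeepRegressionNetwork:
    """Wide&Deep regressor of a per-subject response on feature stacks.

    Parameters
    ----------
    features : ndarray
        Either ``(M, C, d)`` per-subject per-channel feature stacks, or a
        1-D array of ``M`` scalar indicator values (the scalar-ablation
        variant, which removes the concatenation stage).
    targets : ndarray
        Response value per subject (e.g. accuracy at one window length
        or a psi-mapped accuracy summary).
    """

    def __init__(self, features: np.ndarray, targets: np.ndarray):
        features = np.asarray(features, dtype=float)
        targets = np.asarray(targets, dtype=float).ravel()
        self.scalar_variant = features.ndim == 1
        if self.scalar_variant:
            features = features.reshape(-1, 1, 1)
        if features.ndim != 3:
            raise ValueError("features must be (M, C, d) or 1-D scalars")
        if features.shape[0] != targets.size:
            raise ValueError("feature and target counts differ")
        if features.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if not np.isfinite(features).all() or not np.isfinite(targets).all():
            raise ValueError("non-finite inputs")
        self.features = features
        self.targets = targets
        self.arch = build_drn(features.shape[2], features.shape[1],
                              scalar_variant=self.scalar_variant)
        # per-dimension standardization statistics (training contract:
        # computed here, on the data the model was built from)
        self._mu = features.mean(axis=0)
        sd = features.std(axis=0)
        self._sd = np.where(sd > 1e-12, sd, 1.0)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self._mu) / self._sd

    def fit(self, epochs: int = 2000, lr: float = 1e-3,
            l1: float = 1e-3, l2: float = 1e-3,
            tol: float = 1e-5, patience: int = 100,
            seed: int = 0) -> "DRNResults":
        """Full-batch Adam on MAE + elastic-net penalty; deterministic per seed.

        Training stops early once the loss has not improved by more than
        ``tol`` for ``patience`` consecutive epochs.
        """
        X = self._standardize(self.features)
        y = self.targets
        m = X.shape[0]
        params = _init_params(self.arch, np.random.default_rng(seed))
        mom = {k: np.zeros_like(v) for k, v in params.items()}
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        history = []
        best = np.inf
        stall = 0
        converged = False
        for t in range(1, epochs + 1):
            yhat, cache = _forward(params, X)
            err = yhat - y
            loss = float(np.abs(err).mean())
            for k in _WEIGHT_KEYS:
                loss += l1 * float(np.abs(params[k]).sum()) + l2 * float((params[k] ** 2).sum())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {t} (lr={lr}, seed={seed})")
            history.append(loss)
            g = np.sign(err) / m
            grads = _backward(params, cache, g)
            for k in _WEIGHT_KEYS:
                grads[k] = grads[k] + l1 * np.sign(params[k]) + 2.0 * l2 * params[k]
            for k in params:
                mom[k] = b1m * mom[k] + (1 - b1m) * grads[k]
                vel[k] = b2m * vel[k] + (1 - b2m) * grads[k] ** 2
                mhat = mom[k] / (1 - b1m**t)
                vhat = vel[k] / (1 - b2m**t)
                params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            if loss < best - tol:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    converged = True
                    break
        xi_star, _ = _forward(params, X)
        return DRNResults(self, params, xi_star, np.asarray(history), converged, seed)


@dataclass
class DRNResults:
    """Fit results: the extracted indicator, parameters and diagnostics."""

    model: DeepRegressionNetwork
    params: dict[str, np.ndarray]
    xi_star: np.ndarray
    loss_history: np.ndarray
    converged: bool
    seed: int

    @property
    def n_epochs(self) -> int:
        return int(self.loss_history.size)

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1])

    def predict(self, features: np.ndarray) -> np.ndarray:
        """xi* for new subjects, using the training standardization."""
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features.reshape(-1, 1, 1)
        y, _ = _forward(self.params, self.model._standardize(features))
        return y

    def spearman(self, targets: np.ndarray | None = None) -> float:
        """Rank correlation of xi* with the regression targets."""
        t = self.model.targets if targets is None else np.asarray(targets, float)
        return evaluate(self.xi_star, t).r

    def summary(self) -> str:
        a = self.model.arch
        r = self.spearman()
        lines = [
            "Wide&Deep Regression Network Results",
            "=" * 46,
            f"{'No. subjects:':<28}{self.model.features.shape[0]}",
            f"{'Variant:':<28}{'scalar' if a.scalar_variant else 'moment features'}",
            f"{'Channels (C):':<28}{a.n_channels}",
            f"{'Feature length (d):':<28}{a.d}",
            f"{'Branch width (h):':<28}{a.h}",
            f"{'Concat width (h*C):':<28}{a.ct_size}",
            f"{'Hidden width (theta2):':<28}{a.theta2_size}",
            f"{'Epochs run:':<28}{self.n_epochs}",
            f"{'Converged (plateau):':<28}{self.converged}",
            f"{'Final loss (MAE+penalty):':<28}{self.final_loss:.5f}",
            f"{'In-sample Spearman r:':<28}{r:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Response mappings, evaluation and validation
# ---------------------------------------------------------------------------

def psi_map(V: np.ndarray, mode: str = "mean",
            cv_variances: np.ndarray | None = None) -> np.ndarray:
    """Reduce each subject's accuracy vector across window lengths to one target.

    ``mode="mean"``: weighted mean across the window lengths with weights
    proportional to the inverse across-subject variance of each column
    (optionally, pass per-cell ``cv_variances`` of shape (M, 4) to weight
    by each subject's own CV variance instead).  ``mode="pca1"``: score
    on the first principal component of the centred subjects x lengths
    matrix, sign-aligned to correlate positively with the plain mean.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be (n_subjects, n_window_lengths)")
    if mode == "mean":
        if cv_variances is not None:
            w = 1.0 / np.maximum(np.asarray(cv_variances, float), 1e-12)
            return (V * w).sum(axis=1) / w.sum(axis=1)
        var = V.var(axis=0)
        if np.all(var <= 1e-30):
            warnings.warn("zero variance at every window length; using unweighted mean",
                          stacklevel=2)
            return V.mean(axis=1)
        w = 1.0 / np.maximum(var, 1e-30)
        w = w / w.sum()
        return V @ w
    if mode == "pca1":
        if V.shape[0] < 3:
            raise ValueError("PCA1 needs at least 3 subjects")
        centered = V - V.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[0]
        plain = V.mean(axis=1)
        if np.corrcoef(scores, plain)[0, 1] < 0:
            scores = -scores
        return scores
    raise ValueError(f"unknown psi mode {mode!r}")


@dataclass
class RegressionResult:
    """Spearman evaluation of an indicator against the response."""

    r: float
    p_value: float
    mode: str
    predictions: np.ndarray
    targets: np.ndarray
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)


def evaluate(xi: np.ndarray, targets: np.ndarray, mode: str = "in-sample") -> RegressionResult:
    """Spearman rank correlation (average ranks on ties) of xi vs. targets."""
    xi = np.asarray(xi, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if xi.size != targets.size or xi.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(xi) == 0 or np.ptp(targets) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return RegressionResult(np.nan, np.nan, mode, xi, targets, degenerate=True)
    r, p = stats.spearmanr(xi, targets)
    return RegressionResult(float(r), float(p), mode, xi, targets)


def linear_baseline(xi_scalar: np.ndarray, targets: np.ndarray) -> RegressionResult:
    """The linear-correlation comparator: Spearman of the raw scalar indicator."""
    return evaluate(xi_scalar, targets, mode="linear")


def loo_evaluate(features: np.ndarray, targets: np.ndarray,
                 epochs: int = 2000, seed: int = 0,
                 fit_kwargs: dict | None = None) -> RegressionResult:
    """Leave-one-out validation across subjects.

    For each subject the network is refit on the remaining M-1 (feature
    standardization recomputed from the training subjects only) and the
    held-out subject's xi* recorded; the Spearman correlation is taken
    over the M held-out predictions.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    M = targets.size
    if M < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    fit_kwargs = dict(fit_kwargs or {})
    preds = np.empty(M)
    for m in range(M):
        keep = np.arange(M) != m
        model = DeepRegressionNetwork(features[keep], targets[keep])
        res = model.fit(epochs=epochs, seed=seed + m, **fit_kwargs)
        held = features[m:m + 1] if features.ndim > 1 else features[m:m + 1]
        preds[m] = float(res.predict(held)[0])
    out = evaluate(preds, targets, mode="loo")
    out.diagnostics["n_fits"] = M
    return out
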