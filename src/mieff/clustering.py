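"""Subject efficiency groups from accuracy profiles.

Subjects are partitioned by k-means on their accuracy vectors across the
four feature-extraction window lengths; the group count is selected by
the silhouette score (the inertia elbow is reported as a diagnostic).
Groups are labelled I, II, III, ... by decreasing group-mean accuracy.
A fourth, non-predictable group (IV) collects subjects whose
leave-one-out regression residual is atypically large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .drn import RegressionResult

__all__ = ["ClusterResult", "cluster_subjects", "flag_outliers", "assignment_matrix"]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
OUTLIER_GROUP = "IV"


@dataclass
class ClusterResult:
    """Group assignment per subject plus model-selection diagnostics."""

    labels: np.ndarray                    # group names, e.g. "I".."III" (+ "IV")
    k: int
    silhouette: dict[int, float]          # candidate k -> score
    inertia: dict[int, float]             # candidate k -> k-means inertia
    group_means: dict[str, float]         # group -> mean accuracy
    base_labels: np.ndarray | None = None # pre-outlier assignment
    provenance: str = ""

    def to_frame(self, run: str = "") -> pd.DataFrame:
        return pd.DataFrame({"subject": np.arange(self.labels.size),
                             "run": run or self.provenance,
                             "group": self.labels})


def cluster_subjects(accuracy_matrix: np.ndarray,
                     k_candidates: range | tuple = range(2, 7),
                     seed: int = 0, n_init: int = 10,
                     provenance: str = "") -> ClusterResult:
    """k-means over the subjects x window-lengths accuracy matrix.

    The candidate ``k`` maximizing the silhouette score is chosen;
    groups are relabelled by decreasing group-mean accuracy so group I
    always holds the best performers.  A degenerate cohort in which all
    subjects coincide falls back to a single group with a warning.
    """
    V = np.asarray(accuracy_matrix, dtype=float)
    if V.ndim != 2:
        raise ValueError("accuracy matrix must be 2-D (subjects x window lengths)")
    M = V.shape[0]
    ks = [k for k in k_candidates]
    if M <= max(ks):
        raise ValueError("need more subjects than the largest candidate k")
    if np.allclose(V, V[0]):
        warnings.warn("all subjects identical; silhouette undefined, falling back to k=1",
                      stacklevel=2)
        labels = np.array(["I"] * M)
        return ClusterResult(labels, 1, {}, {}, {"I": float(V.mean())},
                             provenance=provenance)
    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(V)
        inertia[k] = float(km.inertia_)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(V, lab))
        fits[k] = lab
    best_k = max(sil, key=sil.get)
    raw = fits[best_k]
    means = {g: float(V[raw == g].mean()) for g in np.unique(raw)}
    order = sorted(means, key=means.get, reverse=True)
    rename = {g: _ROMAN[i] for i, g in enumerate(order)}
    labels = np.array([rename[g] for g in raw])
    group_means = {rename[g]: means[g] for g in order}
    return ClusterResult(labels, best_k, sil, inertia, group_means,
                         provenance=provenance)


def flag_outliers(cluster: ClusterResult, loo_result: RegressionResult,
                  threshold: float = 2.0) -> ClusterResult:
    """Move non-predictable subjects to the outlier group.

    A subject whose absolute leave-one-out residual exceeds
    ``threshold`` times the cohort's median absolute residual is
    reassigned to group IV; the original group is retained in
    ``base_labels``.
    """
    if loo_result.predictions.size != cluster.labels.size:
        raise ValueError("LOO predictions must cover every clustered subject")
    resid = np.abs(loo_result.predictions - loo_result.targets)
    med = float(np.median(resid))
    if med <= 0:
        outlier = np.zeros(resid.size, dtype=bool)
    else:
        outlier = resid > threshold * med
    labels = cluster.labels.copy()
    labels[outlier] = OUTLIER_GROUP
    means = dict(cluster.group_means)
    if outlier.any():
        means[OUTLIER_GROUP] = float(np.mean(loo_result.targets[outlier]))
    return ClusterResult(labels, cluster.k, cluster.silhouette, cluster.inertia,
                         means, base_labels=cluster.labels.copy(),
                         provenance=cluster.provenance)


def assignment_matrix(results: list[ClusterResult],
                      run_names: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subjects x runs label matrix plus pairwise group-exchange counts.

    The exchange count between two runs is the number of subjects whose
    group assignment differs; it supports trial-ablation stability
    studies (removing trials run by run and re-clustering).
    """
    if len(results) != len(run_names):
        raise ValueError("need one name per result")
    sizes = {r.labels.size for r in results}
    if len(sizes) != 1:
        raise ValueError("all results must cover the same subject set")
    table = pd.DataFrame({name: r.labels for name, r in zip(run_names, results)})
    table.index.name = "subject"
    n = len(results)
    ex = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            ex[i, j] = int((results[i].labels != results[j].labels).sum())
    exchanges = pd.DataFrame(ex, index=run_names, columns=run_names)
    return table, exchanges
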