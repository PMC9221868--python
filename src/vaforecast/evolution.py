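"""Disease-evolution analysis: better/worse labelling, DTW clustering,
gradient-boosting classification.

Sequences of unequal length are compared with dynamic time warping
(squared pointwise cost, symmetric steps), so clustering can use the
original irregular series directly. Label 0 marks a good evolution
(visual acuity not declining), label 1 a poor one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.ensemble import GradientBoostingClassifier

from .forecast import grouped_folds
from .records import EyeSeries

__all__ = [
    "EvolutionLabel",
    "DtwResult",
    "label_evolution",
    "dtw_distance",
    "TimeWarpKMeans",
    "kmeans_dtw",
    "cluster_label_agreement",
    "classify_evolution",
]

log = logging.getLogger(__name__)

GOOD, POOR = 0, 1


@dataclass(frozen=True)
class EvolutionLabel:
    """0 = good (amelioration / stable) evolution, 1 = poor (worsening)."""

    label: int

    def __post_init__(self):
        if self.label not in (GOOD, POOR):
            raise ValueError("label must be 0 or 1")


def label_evolution(series: EyeSeries, strategy: str = "first_last") -> EvolutionLabel:
    """Label an eye's evolution from its VA trajectory.

    ``first_last``: poor iff VA at the last visit is strictly below the
    first (ties count as good). ``slope``: poor iff the least-squares
    slope of VA against time is negative.
    """
    va = series.va_values()
    t = series.days_since_first()
    if len(va) < 2:
        raise ValueError("evolution labelling needs >= 2 visits")
    if strategy == "first_last":
        if np.isnan(va[0]) or np.isnan(va[-1]):
            raise ValueError("missing endpoint VA")
        return EvolutionLabel(POOR if va[-1] < va[0] else GOOD)
    if strategy == "slope":
        ok = ~np.isnan(va)
        if ok.sum() < 2:
            raise ValueError("not enough VA values for a slope")
        slope = np.polyfit(t[ok], va[ok], 1)[0]
        return EvolutionLabel(POOR if slope < 0 else GOOD)
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass
class DtwResult:
    """DTW distance plus the optimal warping path (monotone index pairs)."""

    distance: float
    path: list[tuple[int, int]]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> DtwResult:
    """Classic dynamic-programming DTW with squared pointwise cost.

    Handles unequal lengths and multivariate rows; the path starts at
    (0, 0), ends at (n-1, m-1), and moves by (1,0), (0,1) or (1,1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("DTW inputs must be nonempty")
    cost = np.array([[float(np.sum((ai - bj) ** 2)) for bj in b] for ai in a])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        moves = []
        if i > 0 and j > 0:
            moves.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            moves.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            moves.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(moves, key=lambda t: t[0])
        path.append((i, j))
    return DtwResult(float(acc[n - 1, m - 1]), path[::-1])


class TimeWarpKMeans(BaseEstimator, ClusterMixin):
    """K-means-style clustering of unequal-length series under DTW.

    Centres are medoids (the member minimising the within-cluster DTW
    sum), which keeps the objective exact under the DTW metric; the
    within-cluster objective is non-increasing across iterations.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 50, seed: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, series_list: list[np.ndarray], y=None):
        if self.n_clusters < 2:
            raise ValueError("need k >= 2 clusters")
        n = len(series_list)
        if n < self.n_clusters:
            raise ValueError(f"need at least k={self.n_clusters} series, got {n}")
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dtw_distance(series_list[i], series_list[j]).distance
        rng = np.random.default_rng(self.seed)
        medoids = list(rng.choice(n, size=self.n_clusters, replace=False))
        labels = np.argmin(d[:, medoids], axis=1)
        objective = np.inf
        history = []
        for _ in range(self.max_iter):
            new_medoids = []
            for c in range(self.n_clusters):
                members = np.flatnonzero(labels == c)
                if len(members) == 0:
                    new_medoids.append(medoids[c])
                    continue
                within = d[np.ix_(members, members)].sum(axis=1)
                new_medoids.append(int(members[np.argmin(within)]))
            new_labels = np.argmin(d[:, new_medoids], axis=1)
            new_obj = float(sum(d[i, new_medoids[c]] for i, c in enumerate(new_labels)))
            history.append(new_obj)
            if new_obj > objective + 1e-12:
                break
            converged = np.array_equal(new_labels, labels) and new_medoids == medoids
            medoids, labels, objective = new_medoids, new_labels, new_obj
            if converged:
                break
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = objective
        self.objective_history_ = history
        self.distance_matrix_ = d
        return self

    def fit_predict(self, series_list, y=None):
        return self.fit(series_list).labels_


def kmeans_dtw(series_list: list[np.ndarray], k: int = 2, seed: int = 0) -> np.ndarray:
    """Cluster assignments of unequal-length series under the DTW metric."""
    return TimeWarpKMeans(n_clusters=k, seed=seed).fit_predict(series_list)


def cluster_label_agreement(assignments: np.ndarray, labels: np.ndarray) -> float:
    """Agreement of a 2-cluster assignment with binary labels, up to relabelling."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    acc = float(np.mean(assignments == labels))
    return max(acc, 1.0 - acc)


def classify_evolution(
    x: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Cross-validated gradient-boosting classification of evolution labels.

    ``x`` holds one prior visit's features per sample. Returns the 2x2
    confusion matrix with columns = actual label and rows = predicted
    label, plus the pooled accuracy.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        log.warning("single-class labels: classification degenerate")
        return {"accuracy": 1.0, "confusion": np.zeros((2, 2), dtype=int), "degenerate": True}
    if groups is None:
        groups = np.arange(len(labels))
    n_groups = len(set(groups))
    folds = grouped_folds(groups, min(n_folds, n_groups), seed=seed)
    preds = np.full(len(labels), -1)
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
        if len(set(labels[train_idx])) < 2:
            preds[test_idx] = labels[train_idx][0]
            continue
        clf = GradientBoostingClassifier(random_state=seed)
        clf.fit(x[train_idx], labels[train_idx])
        preds[test_idx] = clf.predict(x[test_idx])
    confusion = np.zeros((2, 2), dtype=int)
    for actual, pred in zip(labels, preds):
        confusion[pred, actual] += 1  # columns = actual
    accuracy = float(np.mean(preds == labels))
    return {"accuracy": accuracy, "confusion": confusion, "degenerate": False}
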