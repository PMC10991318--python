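"""K-means clustering with smallest-cluster outlier elimination.

The clustering loop is the classic Lloyd iteration — random-record center
initialization, nearest-center assignment by Euclidean distance, mean-update
of centers — run to convergence of the within-cluster sum-of-squares
criterion

    J = sum_r sum_{x in C_r} ||x - S_r||^2

with stopping rule |J(I) - J(I-1)| < xi.  Multiple seeded restarts guard
against poor initializations.  Outlier screening then removes every cluster
whose size falls below a fraction of n (planted contamination in screening
cohorts tends to form small, displaced clusters), and the silhouette index is
recomputed on a refit of the surviving records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterModel",
    "OutlierReport",
    "kmeans_fit",
    "sse_criterion",
    "silhouette_index",
    "remove_outliers",
]


@dataclass
class ClusterModel:
    centers: np.ndarray          # (K, d)
    assignments: np.ndarray      # (n,) cluster index per record
    sse_history: list[float]     # J per iteration (non-increasing)
    n_iterations: int
    tolerance: float
    seed: int
    converged: bool

    @property
    def sse(self) -> float:
        return self.sse_history[-1]

    def cluster_sizes(self) -> np.ndarray:
        K = self.centers.shape[0]
        return np.bincount(self.assignments, minlength=K)


@dataclass
class OutlierReport:
    removed_indices: np.ndarray
    removed_cluster_ids: tuple[int, ...]
    silhouette_before: float
    silhouette_after: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "removed_indices": self.removed_indices.tolist(),
            "removed_cluster_ids": list(self.removed_cluster_ids),
            "silhouette_before": self.silhouette_before,
            "silhouette_after": self.silhouette_after,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")


def sse_criterion(X: np.ndarray, centers: np.ndarray, assignments: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to assigned centers."""
    diff = X - centers[assignments]
    return float(np.sum(diff * diff))


def _single_run(
    X: np.ndarray,
    K: int,
    tolerance: float,
    max_iter: int,
    rng: np.random.Generator,
    init_indices: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    n = X.shape[0]
    if init_indices is None:
        init_indices = rng.choice(n, size=K, replace=False)
    centers = X[np.asarray(init_indices)].astype(float).copy()
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # assignment: nearest center, lowest index wins on exact ties
        d2 = cdist(X, centers, metric="sqeuclidean")
        assignments = np.argmin(d2, axis=1)
        # mean update; empty clusters re-seeded from the farthest record
        for r in range(K):
            members = assignments == r
            if members.any():
                centers[r] = X[members].mean(axis=0)
        empty = [r for r in range(K) if not np.any(assignments == r)]
        if empty:
            resid = np.sum((X - centers[assignments]) ** 2, axis=1)
            for r in empty:
                far = int(np.argmax(resid))
                centers[r] = X[far]
                resid[far] = -np.inf  # don't reuse the same record
        J = sse_criterion(X, centers, assignments)
        history.append(J)
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tolerance:
            converged = True
            break
    return centers, assignments, history, it, converged


def kmeans_fit(
    X: np.ndarray,
    K: int,
    tolerance: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_restarts: int = 5,
    init_indices: np.ndarray | None = None,
) -> ClusterModel:
    """Fit K clusters by restarted Lloyd iterations.

    Centers start at K distinct randomly chosen records (or at the rows named
    by ``init_indices``, in which case a single run is performed).  The run
    with the lowest final criterion J is returned.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of records n={n}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rng = np.random.default_rng(seed)
    best = None
    runs = 1 if init_indices is not None else max(1, n_restarts)
    for _ in range(runs):
        result = _single_run(X, K, tolerance, max_iter, rng, init_indices)
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    centers, assignments, history, iters, converged = best
    return ClusterModel(
        centers=centers, assignments=assignments, sse_history=history,
        n_iterations=iters, tolerance=tolerance, seed=seed, converged=converged,
    )


def silhouette_index(X: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) over all records.

    ``a`` is the mean distance to the record's own cluster (excluding itself),
    ``b`` the smallest mean distance to any other cluster.  Records in
    singleton clusters contribute 0.
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    sizes = {lab: int(np.sum(assignments == lab)) for lab in labels}
    scores = np.zeros(n)
    for lab in labels:
        mask = assignments == lab
        if sizes[lab] == 1:
            continue  # singleton: score 0
        within = D[np.ix_(mask, mask)]
        a = within.sum(axis=1) / (sizes[lab] - 1)
        b = np.full(int(mask.sum()), np.inf)
        for other in labels:
            if other == lab:
                continue
            between = D[np.ix_(mask, assignments == other)].mean(axis=1)
            b = np.minimum(b, between)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        scores[mask] = s
    return float(scores.mean())


def remove_outliers(
    X: np.ndarray,
    K: int = 3,
    min_cluster_fraction: float = 0.10,
    tolerance: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_restarts: int = 5,
    standardize: bool = True,
) -> tuple[np.ndarray, OutlierReport]:
    """Delete every cluster smaller than ``min_cluster_fraction * n``.

    Distances are computed on internally z-scored columns by default, so
    mixed-unit raw features cannot dominate; the returned ``X_clean`` contains
    the surviving rows of the *original* X.  The silhouette index is computed
    before removal and again on a refit of the surviving records.
    """
    X = np.asarray(X, dtype=float)
    if K < 2:
        raise ValueError("outlier screening needs K >= 2")
    n = X.shape[0]
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    else:
        Z = X
    model = kmeans_fit(Z, K, tolerance, max_iter, seed, n_restarts)
    sil_before = silhouette_index(Z, model.assignments)
    sizes = model.cluster_sizes()
    threshold = min_cluster_fraction * n
    removed_ids = tuple(int(r) for r in range(K) if sizes[r] < threshold)
    removed = np.flatnonzero(np.isin(model.assignments, removed_ids))
    if removed.size >= 0.5 * n:
        raise ValueError(
            f"removal of {removed.size}/{n} records (>= 50%) refused; "
            f"check K={K} and min_cluster_fraction={min_cluster_fraction}"
        )
    keep = np.setdiff1d(np.arange(n), removed)
    Z_clean = Z[keep]
    refit = kmeans_fit(Z_clean, min(K, len(keep)), tolerance, max_iter, seed, n_restarts)
    sil_after = silhouette_index(Z_clean, refit.assignments)
    report = OutlierReport(
        removed_indices=removed,
        removed_cluster_ids=removed_ids,
        silhouette_before=sil_before,
        silhouette_after=sil_after,
    )
    return X[keep], report
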