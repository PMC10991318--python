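"""Synthetic minority oversampling (SMOTE) by nearest-neighbour interpolation.

Each synthetic record is ``x_i + u * (x_nn - x_i)`` where ``x_i`` is a
uniformly drawn minority record, ``x_nn`` one of its k Euclidean nearest
minority neighbours (uniformly drawn), and ``u ~ Uniform(0, 1)`` — so every
synthetic point lies on a segment of the minority k-NN graph.  Intended for
the training partition only; balancing held-out data would invalidate
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data import Dataset

__all__ = ["SmoteConfig", "generate_synthetic", "balance"]


@dataclass(frozen=True)
class SmoteConfig:
    """Oversampling parameters.

    ``target="parity"`` raises the minority count to the majority count;
    an integer target requests that many synthetic records instead.
    """

    k_neighbors: int = 5
    target: str | int = "parity"
    seed: int = 0
    round_discrete: bool = False  # optional post-step: round binary/ordinal columns

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def generate_synthetic(
    X_minority: np.ndarray, n_new: int, config: SmoteConfig
) -> np.ndarray:
    """Interpolate ``n_new`` synthetic records within the minority class."""
    X_minority = np.asarray(X_minority, dtype=float)
    n_min = X_minority.shape[0]
    if n_min <= config.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={config.k_neighbors}"
        )
    if n_new == 0:
        return np.empty((0, X_minority.shape[1]))
    rng = np.random.default_rng(config.seed)
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X_minority)
    # column 0 is the point itself; keep the k true neighbours
    neighbor_idx = nn.kneighbors(X_minority, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, config.k_neighbors, size=n_new)
    u = rng.random(n_new)
    x_i = X_minority[base]
    x_nn = X_minority[neighbor_idx[base, pick]]
    return x_i + u[:, None] * (x_nn - x_i)


def balance(ds: Dataset, config: SmoteConfig = SmoteConfig()) -> Dataset:
    """Append synthetic minority records until the classes reach parity.

    Original records (both classes) are untouched; synthetic records carry
    the minority label and are appended after the originals.  An already
    balanced dataset is returned unchanged.
    """
    counts = ds.class_counts()
    if len(counts) < 2:
        raise ValueError("balance requires both classes present")
    minority = min(counts, key=lambda c: (counts[c], c))
    majority = 1 - minority
    if config.target == "parity":
        n_new = counts[majority] - counts[minority]
    else:
        n_new = int(config.target)
    if n_new <= 0:
        return Dataset(ds.X.copy(), ds.y.copy(), ds.schema)
    X_min = ds.X[ds.y == minority]
    X_new = generate_synthetic(X_min, n_new, config)
    if config.round_discrete:
        for k, kind in enumerate(ds.schema.feature_kinds):
            if kind in ("binary", "ordinal"):
                X_new[:, k] = np.round(X_new[:, k])
    X = np.vstack([ds.X, X_new])
    y = np.concatenate([ds.y, np.full(n_new, minority, dtype=int)])
    return Dataset(X, y, ds.schema)
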