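"""Recursive feature elimination (RFE) with a full elimination-order ranking.

A base ranker (L2 logistic regression on standardized features, or a
decision tree) is refit on the surviving features each round and the least
important feature — smallest |coefficient| or impurity importance — is
dropped.  Elimination continues to the last feature so that the result is a
total order: rank 1 is the feature eliminated last (most important), rank d
the first to go.  The selected subset of size ``n_select`` is exactly the
features with rank <= n_select, which makes selections nested across
``n_select`` values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .data import Dataset

__all__ = ["RfeResult", "rfe_rank", "apply_selection"]


@dataclass
class RfeResult:
    ranking: np.ndarray          # (d,) 1 = most important (eliminated last)
    selected_mask: np.ndarray    # (d,) bool, exactly n_select True
    importance_trace: list[dict[int, float]]  # per-round {feature: importance}
    n_select: int

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected_mask)

    def table(self, feature_names) -> list[tuple[str, bool]]:
        """Two-column (Feature, Selected) summary table."""
        return [
            (name, bool(sel)) for name, sel in zip(feature_names, self.selected_mask)
        ]


def _importances(
    X: np.ndarray, y: np.ndarray, base_ranker: str, seed: int, round_index: int
) -> np.ndarray:
    if base_ranker == "logistic":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = sd <= 1e-12 * (1.0 + np.abs(mu))
        Z = (X - mu) / np.where(~constant, sd, 1.0)
        Z[:, constant] = 0.0  # zero column -> |coefficient| exactly 0
        model = LogisticRegression(max_iter=2000, random_state=seed)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Z, y)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"logistic ranker failed to converge in round {round_index}"
                ) from exc
        return np.abs(model.coef_[0])
    if base_ranker == "tree":
        model = DecisionTreeClassifier(random_state=seed)
        model.fit(X, y)
        return model.feature_importances_
    raise ValueError(f"unknown base_ranker {base_ranker!r}")


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_select: int,
    base_ranker: str = "logistic",
    step: int = 1,
    seed: int = 0,
) -> RfeResult:
    """Rank features by recursive elimination; select the top ``n_select``.

    Importance ties are broken by eliminating the higher column index, so the
    procedure is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    d = X.shape[1]
    if not 1 <= n_select <= d:
        raise ValueError(f"n_select must lie in [1, {d}], got {n_select}")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    surviving = list(range(d))
    elimination_order: list[int] = []  # first eliminated first
    trace: list[dict[int, float]] = []
    round_index = 0
    while len(surviving) > 1:
        round_index += 1
        imp = _importances(X[:, surviving], y, base_ranker, seed, round_index)
        trace.append({f: float(w) for f, w in zip(surviving, imp)})
        n_drop = min(step, len(surviving) - 1)
        # least important first; ties broken toward the higher original index
        order = sorted(
            range(len(surviving)), key=lambda j: (imp[j], -surviving[j])
        )
        drop = sorted((surviving[j] for j in order[:n_drop]), reverse=True)
        for f in drop:
            surviving.remove(f)
            elimination_order.append(f)
    elimination_order.extend(surviving)  # the survivor, eliminated "last"

    ranking = np.empty(d, dtype=int)
    for pos, feature in enumerate(elimination_order):
        ranking[feature] = d - pos  # last eliminated gets rank 1
    selected_mask = ranking <= n_select
    return RfeResult(
        ranking=ranking, selected_mask=selected_mask,
        importance_trace=trace, n_select=n_select,
    )


def apply_selection(ds: Dataset, result: RfeResult) -> Dataset:
    """Restrict a dataset to the selected feature columns (original order)."""
    if result.selected_mask.shape[0] != ds.n_features:
        raise ValueError(
            f"mask covers {result.selected_mask.shape[0]} features, "
            f"dataset has {ds.n_features}"
        )
    idx = result.selected_indices()
    names = [ds.schema.feature_names[i] for i in idx]
    return Dataset(ds.X[:, idx].copy(), ds.y.copy(), ds.schema.subset(names))
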