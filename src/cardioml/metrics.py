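"""Confusion-matrix metrics, ROC/AUC, baseline classifiers, and ablations.

Accuracy, recall, precision and F1 follow the standard confusion-count
formulas::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 TP / (2 TP + FP + FN)

The ROC curve is built by a threshold sweep over the unique scores (tied
scores collapse to a single step) and the AUC by the trapezoid rule, which is
algebraically identical to the Mann–Whitney pair-counting statistic with half
credit for ties — a property the test suite checks exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .data import Dataset

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_scores",
    "baselines",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """One classifier's full evaluation on a test partition."""

    model_name: str
    counts: ConfusionCounts
    accuracy: float
    recall: float
    precision: float
    f1: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR)
    auc: float
    degenerate: bool = False  # a zero-denominator metric was reported as 0

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1, "auc": self.auc,
            "degenerate": self.degenerate,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels and hard predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} labels vs {y_pred.shape} predictions"
        )
    for arr, what in ((y_true, "labels"), (y_pred, "predictions")):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{what} must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, bool]:
    """(accuracy, recall, precision, f1, degenerate_flag) from counts.

    Zero-denominator cases (no actual positives / no predicted positives)
    report the affected metric as 0.0 and set the flag.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / counts.total
    degenerate = False
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if 2 * tp + fp + fn > 0:
        f1 = 2 * tp / (2 * tp + fp + fn)
    else:
        f1, degenerate = 0.0, True
    return accuracy, recall, precision, f1, degenerate


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep, and trapezoid AUC.

    Thresholds are the unique score values in decreasing order; tied scores
    are a single step, so the curve is a polyline from (0,0) to (1,1) and the
    trapezoid area equals the Mann–Whitney statistic with ties at half credit.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score block
    last_of_block = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp_cum[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_block] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_scores(
    y_true, scores, model_name: str = "model", threshold: float = 0.5
) -> EvalReport:
    """Full report (counts, four metrics, ROC, AUC) from probability scores."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    counts = confusion(y_true, y_pred)
    accuracy, recall, precision, f1, degenerate = metrics(counts)
    roc_points, auc = roc_auc(y_true, scores)
    return EvalReport(
        model_name=model_name, counts=counts, accuracy=accuracy,
        recall=recall, precision=precision, f1=f1,
        roc_points=roc_points, auc=auc, degenerate=degenerate,
    )


def baselines(
    train: Dataset,
    test: Dataset,
    which: tuple[str, ...] = ("LR", "KNN", "NB"),
    knn_k: int = 5,
    seed: int = 0,
) -> list[EvalReport]:
    """Conventional classifiers on identical features/splits as the main model.

    LR = L2 logistic regression, KNN = Euclidean k-nearest neighbours
    (default k = 5), NB = Gaussian naive Bayes.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("training partition must contain both classes")
    factories = {
        "LR": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "KNN": lambda: KNeighborsClassifier(n_neighbors=knn_k),
        "NB": lambda: GaussianNB(),
    }
    unknown = set(which) - set(factories)
    if unknown:
        raise ValueError(f"unknown baselines {sorted(unknown)}")
    reports = []
    for name in which:
        model = factories[name]()
        model.fit(train.X, train.y)
        scores = model.predict_proba(test.X)[:, 1]
        reports.append(evaluate_scores(test.y, scores, model_name=name))
    return reports
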