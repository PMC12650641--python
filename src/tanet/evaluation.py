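"""Classification metrics and cross-run aggregation.

All metrics are computed from the confusion matrix (rows = true class,
columns = predicted): accuracy is the trace fraction; F1 is
``TP / (TP + (FP + FN) / 2)`` per class, macro-averaged for multiclass;
Cohen's kappa is ``(P0 - Pe) / (1 - Pe)`` with the chance agreement ``Pe``
taken from the matrix marginals.  The micro-averaged ROC AUC flattens the
one-vs-rest score matrix and integrates the ROC curve by the trapezoidal
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = ["confusion_matrix", "accuracy", "f1_score", "cohen_kappa",
           "roc_auc_micro", "EvaluationReport", "evaluate_predictions",
           "aggregate_runs", "paired_t_test", "wilcoxon_test",
           "accuracy_confidence_interval"]

logger = logging.getLogger(__name__)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int | None = None) -> np.ndarray:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def f1_score(cm: np.ndarray, averaging: str = "macro",
             positive_class: int = 1) -> float:
    """Per-class ``TP / (TP + 0.5 (FP + FN))``; ``averaging`` is ``macro``
    (unweighted class mean) or ``binary`` (the positive class only).  A
    class with no true and no predicted samples contributes F1 = 0."""
    cm = np.asarray(cm, dtype=float)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = tp + 0.5 * (fp + fn)
    f1 = np.zeros_like(tp)
    nonzero = denom > 0
    f1[nonzero] = tp[nonzero] / denom[nonzero]
    if (~nonzero).any():
        logger.info("classes %s absent from truth and predictions: F1 := 0",
                    np.flatnonzero(~nonzero).tolist())
    if averaging == "binary":
        return float(f1[positive_class])
    if averaging == "macro":
        return float(f1.mean())
    raise ValueError(f"unknown averaging {averaging!r}")


def cohen_kappa(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    p0 = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / n ** 2)
    if pe >= 1.0:
        raise ValueError("degenerate matrix: chance agreement Pe = 1, "
                         "kappa undefined")
    return float((p0 - pe) / (1.0 - pe))


def roc_auc_micro(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-rest micro-averaged AUC from per-class probability scores
    (n, C): binary indicators and scores are flattened and the ROC curve
    integrated trapezoidally."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    n_classes = scores.shape[1]
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC is undefined with a single observed class")
    onehot = np.eye(n_classes)[labels]
    fpr, tpr, _ = roc_curve(onehot.ravel(), scores.ravel())
    return float(np.trapezoid(tpr, fpr))


@dataclass
class EvaluationReport:
    """Metrics of one fold/run plus optional per-fold breakdown."""

    accuracy: float
    f1: float
    kappa: float
    auc: float | None
    confusion: np.ndarray
    n_samples: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "kappa": self.kappa,
                "auc": self.auc, "n_samples": self.n_samples,
                "confusion": self.confusion.tolist()}


def evaluate_predictions(y_true: np.ndarray, probs: np.ndarray,
                         n_classes: int | None = None) -> EvaluationReport:
    probs = np.atleast_2d(np.asarray(probs))
    y_pred = probs.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, n_classes or probs.shape[1])
    try:
        auc = roc_auc_micro(probs, y_true)
    except ValueError:
        auc = None
    return EvaluationReport(accuracy=accuracy(cm), f1=f1_score(cm),
                            kappa=cohen_kappa(cm), auc=auc, confusion=cm,
                            n_samples=len(y_true))


def aggregate_runs(reports: list[EvaluationReport]) -> dict:
    """Mean and sample standard deviation (n-1 denominator; 0 for a single
    run) per metric; confusion matrices are summed then row-normalised."""
    if not reports:
        raise ValueError("need at least one report")

    def stat(values):
        values = [v for v in values if v is not None]
        if not values:
            return {"mean": None, "sd": None}
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return {"mean": mean, "sd": sd}

    summed = np.sum([r.confusion for r in reports], axis=0).astype(float)
    rows = summed.sum(axis=1, keepdims=True)
    normalised = np.divide(summed, rows, out=np.zeros_like(summed),
                           where=rows > 0)
    return {
        "accuracy": stat([r.accuracy for r in reports]),
        "f1": stat([r.f1 for r in reports]),
        "kappa": stat([r.kappa for r in reports]),
        "auc": stat([r.auc for r in reports]),
        "confusion_normalized": normalised,
        "n_runs": len(reports),
    }


def accuracy_confidence_interval(values, level: float = 0.95):
    """t-distribution CI of the mean across folds/runs."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if len(values) < 2:
        return (mean, mean)
    sem = values.std(ddof=1) / np.sqrt(len(values))
    t = stats.t.ppf(0.5 + level / 2.0, df=len(values) - 1)
    return (float(mean - t * sem), float(mean + t * sem))


def paired_t_test(a, b) -> float:
    """p-value of the paired t-test between two matched metric vectors;
    identical vectors give p = 1."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def wilcoxon_test(a, b) -> float:
    """p-value of the Wilcoxon signed-rank test; identical vectors give 1."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.allclose(a, b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)
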