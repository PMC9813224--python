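"""Classifier evaluation: confusion matrices, sensitivity/specificity, ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    """Evaluation summary for one classification task.

    ``confusion`` holds counts (rows = true class); ``confusion_percent``
    normalizes each true-class row to 100. ``sensitivity`` is recall on class
    1 (carcinoma), ``specificity`` recall on class 0 (paracancer); both are
    None for multiclass tasks. ``roc`` is (fpr, tpr, thresholds) from a
    threshold sweep on the class-1 probability, and ``auc`` its trapezoidal
    area; both are None (missing) when the truth contains a single class or
    more than two classes.
    """

    classes: list
    confusion: np.ndarray
    confusion_percent: np.ndarray
    accuracy: float
    sensitivity: float | None = None
    specificity: float | None = None
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    auc: float | None = None


def _roc_curve(y: np.ndarray, score: np.ndarray):
    """ROC by sweeping the decision threshold over every observed score."""
    order = np.argsort(-score, kind="stable")
    y = y[order]
    score = score[order]
    distinct = np.r_[np.flatnonzero(np.diff(score)), len(score) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    p, n = y.sum(), len(y) - y.sum()
    tpr = np.r_[0.0, tps / p]
    fpr = np.r_[0.0, fps / n]
    thresholds = np.r_[np.inf, score[distinct]]
    return fpr, tpr, thresholds


def evaluate(
    y_true: np.ndarray, proba: np.ndarray, classes: list | None = None
) -> EvalReport:
    """Score predictions against truth.

    ``proba`` is (n, n_classes) softmax output (or any per-class scores whose
    argmax is the hard prediction). Hard labels are the argmax; for binary
    tasks the ROC sweeps the class-1 probability.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or len(y_true) != len(proba):
        raise ValueError("probabilities must be (n, n_classes) aligned with truth")
    k = proba.shape[1]
    classes = classes if classes is not None else list(range(k))
    y_pred = proba.argmax(axis=1)

    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    row = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        percent = np.where(row > 0, confusion / np.maximum(row, 1) * 100.0, 0.0)
    accuracy = float((y_pred == y_true).mean())

    sens = spec = auc = roc = None
    if k == 2:
        if confusion[1].sum() > 0:
            sens = float(confusion[1, 1] / confusion[1].sum())
        if confusion[0].sum() > 0:
            spec = float(confusion[0, 0] / confusion[0].sum())
        if len(np.unique(y_true)) == 2:
            fpr, tpr, thr = _roc_curve(y_true, proba[:, 1])
            roc = (fpr, tpr, thr)
            auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(
        classes=list(classes),
        confusion=confusion,
        confusion_percent=percent,
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        roc=roc,
        auc=auc,
    )
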