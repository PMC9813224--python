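"""Thin comparator classifiers run on the same patient-level splits.

These delegate to established learners (PLS-DA via scikit-learn's
PLSRegression, random forest via scikit-learn, gradient boosting via
XGBoost) and exist only to benchmark the CNN under an identical protocol;
they share the evaluation path of :func:`ramanhisto.cnn.evaluate`.
"""

from __future__ import annotations

import numpy as np

from .metrics import EvalReport, evaluate
from .splits import class_weights

__all__ = ["fit_baseline_classifier", "COMPARATOR_METHODS"]

COMPARATOR_METHODS = ("plsda", "random_forest", "gradient_boosting")


def _proba_from_scores(scores: np.ndarray) -> np.ndarray:
    # PLS-DA regresses one-hot targets; map scores to a simplex via softmax
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_baseline_classifier(
    method: str,
    train_set: tuple[np.ndarray, np.ndarray],
    test_set: tuple[np.ndarray, np.ndarray],
    weighted: bool = True,
    seed: int = 0,
    classes: list | None = None,
) -> EvalReport:
    """Fit one comparator and evaluate it on the held-out spectra."""
    X_train, y_train = train_set
    X_test, y_test = test_set
    y_train = np.asarray(y_train, dtype=int)
    n_classes = int(max(y_train.max(), np.asarray(y_test).max())) + 1
    sample_weight = None
    if weighted:
        cw = class_weights(y_train)
        sample_weight = np.array([cw[c] for c in y_train])

    if method == "plsda":
        from sklearn.cross_decomposition import PLSRegression

        onehot = np.eye(n_classes)[y_train]
        if sample_weight is not None:
            onehot = onehot * 1.0  # PLS has no sample weights; classes enter via one-hot
        n_comp = int(min(10, X_train.shape[1], len(y_train) - 1))
        pls = PLSRegression(n_components=n_comp)
        pls.fit(X_train, onehot)
        proba = _proba_from_scores(np.asarray(pls.predict(X_test)))
    elif method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(
            n_estimators=200,
            random_state=seed,
            class_weight="balanced" if weighted else None,
        )
        rf.fit(X_train, y_train)
        proba = _full_proba(rf.predict_proba(X_test), rf.classes_, n_classes)
    elif method == "gradient_boosting":
        from xgboost import XGBClassifier

        xgb = XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            verbosity=0,
        )
        xgb.fit(X_train, y_train, sample_weight=sample_weight)
        proba = _full_proba(xgb.predict_proba(X_test), np.arange(n_classes), n_classes)
    else:
        raise ValueError(f"unknown comparator {method!r}; expected one of {COMPARATOR_METHODS}")
    return evaluate(np.asarray(y_test, dtype=int), proba, classes)


def _full_proba(proba: np.ndarray, fitted_classes, n_classes: int) -> np.ndarray:
    if proba.ndim == 1:
        proba = np.c_[1 - proba, proba]
    full = np.zeros((proba.shape[0], n_classes))
    for j, c in enumerate(np.asarray(fitted_classes, dtype=int)):
        full[:, c] = proba[:, j]
    return full
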