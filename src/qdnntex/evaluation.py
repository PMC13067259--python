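"""Confusion matrices, classification metrics and cross-validation.

Multiclass precision/sensitivity/specificity are macro one-vs-rest: for
each class the binary (TP, TN, FP, FN) counts are formed against the
rest and the per-class metrics averaged without weighting.  Any 0/0
metric denominator yields 0 by convention, so all metrics are total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass
class MetricsReport:
    """The four headline metrics plus per-class detail."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    per_class: dict = field(default_factory=dict)
    fold: int | None = None

    def to_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "precision": self.precision,
               "sensitivity": self.sensitivity, "specificity": self.specificity}
        if self.per_class:
            out["per_class"] = self.per_class
        if self.fold is not None:
            out["fold"] = self.fold
        return out


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        return np.zeros((n_classes, n_classes), dtype=int)
    for arr in (y_true, y_pred):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError("label out of range [0, n_classes-1]")
    return skmetrics.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def binary_metrics(TP: int, TN: int, FP: int, FN: int) -> MetricsReport:
    """Accuracy, precision, sensitivity (recall), specificity from the
    four binary counts."""
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("counts must be >= 0")
    total = TP + TN + FP + FN
    return MetricsReport(
        accuracy=_safe_div(TP + TN, total),
        precision=_safe_div(TP, TP + FP),
        sensitivity=_safe_div(TP, TP + FN),
        specificity=_safe_div(TN, TN + FP),
    )


def one_vs_rest_counts(cm: np.ndarray, c: int) -> tuple:
    """Binary (TP, TN, FP, FN) for class ``c`` against the rest."""
    cm = np.asarray(cm)
    TP = cm[c, c]
    FN = cm[c, :].sum() - TP
    FP = cm[:, c].sum() - TP
    TN = cm.sum() - TP - FN - FP
    return int(TP), int(TN), int(FP), int(FN)


def macro_metrics(cm: np.ndarray) -> MetricsReport:
    """Macro-averaged one-vs-rest metrics of a C x C confusion matrix."""
    cm = np.asarray(cm)
    C = cm.shape[0]
    if cm.ndim != 2 or cm.shape[1] != C or C < 2:
        raise ValueError("confusion matrix must be square with C >= 2")
    per_class = {c: binary_metrics(*one_vs_rest_counts(cm, c)) for c in range(C)}
    return MetricsReport(
        accuracy=float(np.mean([m.accuracy for m in per_class.values()])),
        precision=float(np.mean([m.precision for m in per_class.values()])),
        sensitivity=float(np.mean([m.sensitivity for m in per_class.values()])),
        specificity=float(np.mean([m.specificity for m in per_class.values()])),
        per_class={f"class_{c}": m.to_dict() for c, m in per_class.items()},
    )


def evaluate_predictions(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Macro metrics, with plain multiclass accuracy substituted for the
    one-vs-rest accuracy average in ``per_class['overall_accuracy']``."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    report = macro_metrics(cm)
    report.per_class["overall_accuracy"] = float(
        (np.asarray(y_true) == np.asarray(y_pred)).mean())
    report.per_class["confusion"] = cm.tolist()
    return report


def kfold_split(n: int, k: int, labels=None, seed: int = 0,
                stratified: bool = True) -> list:
    """Seeded k-fold partition of ``range(n)`` into validation index sets.

    Stratified by default (requires every class to hold >= k members);
    folds differ in size by at most one and are pairwise disjoint.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        if labels is None:
            raise ValueError("stratified splitting needs labels")
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(f"every class needs >= {k} members for stratified folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [val for _, val in splitter.split(np.zeros(n), labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in splitter.split(np.zeros(n))]


def run_cv(X, y, model_factory, k: int = 5, seed: int = 0,
           stratified: bool = True):
    """Stratified k-fold cross-validation of a model factory.

    ``model_factory(fold_index)`` must return an unfitted estimator with
    ``fit(X, y)`` and ``predict(X)``.  For each fold the model is fitted
    on the k-1 training folds only and scored on the held-out fold, so
    any internal feature weighting or selection sees training rows only.

    Returns ``(per_fold_reports, mean_report)``; the mean report is the
    arithmetic mean of the per-fold headline metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    folds = kfold_split(n, k, labels=y, seed=seed, stratified=stratified)
    classes = np.unique(y)
    n_classes = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}

    reports = []
    for fold_idx, val_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        model = model_factory(fold_idx)
        model.fit(X[train_mask], y[train_mask])
        y_pred = model.predict(X[val_idx])
        yt = np.asarray([class_index[v] for v in y[val_idx]])
        yp = np.asarray([class_index[v] for v in y_pred])
        report = evaluate_predictions(yt, yp, n_classes)
        report.fold = fold_idx
        reports.append(report)

    mean = MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        per_class={"overall_accuracy": float(np.mean(
            [r.per_class["overall_accuracy"] for r in reports]))},
    )
    return reports, mean
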