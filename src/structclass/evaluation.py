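"""Confusion-matrix metrics and resampling evaluation harnesses.

Per-class sensitivity, specificity and Matthews correlation coefficient
are computed one-vs-rest from a 4 x 4 confusion matrix (rows = true
class, columns = predicted, fixed class order).  Multi-class agreement
is summarised by the generalized squared correlation

    GC^2 = chi^2 / (N * (K - 1)),   K = 4 classes,

which is 0 when predictions are independent of the truth and 1 for any
perfect classification.  Stratified 10-fold cross-validation and the
jackknife (leave-one-out) retrain the full model per split and pool the
held-out predictions into a single confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import DomainDataset, StructuralClassModel, decide
from .targets import CLASSES, TargetParams

__all__ = [
    "MetricsReport",
    "confusion",
    "class_metrics",
    "gc2",
    "overall_accuracy",
    "report_from_confusion",
    "cross_validate",
    "jackknife",
]

logger = logging.getLogger(__name__)

K_CLASSES = len(CLASSES)


def confusion(true_labels, predicted_labels) -> np.ndarray:
    """4 x 4 count matrix, rows true / columns predicted, fixed order."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    index = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((K_CLASSES, K_CLASSES), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown class label in pair ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


def class_metrics(cm: np.ndarray, class_label: str) -> tuple[float, float, float]:
    """One-vs-rest (sensitivity, specificity, MCC) for one class."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    i = CLASSES.index(class_label)
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    if tp + fn == 0:
        logger.warning("class %s absent from the truth; Sn undefined", class_label)
        sn = float("nan")
    else:
        sn = tp / (tp + fn)
    sp = tn / (tn + fp) if tn + fp > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return float(sn), float(sp), float(mcc)


def gc2(cm: np.ndarray) -> float:
    """Generalized squared correlation, chi^2 / (N (K-1))."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    row, col = cm.sum(axis=1), cm.sum(axis=0)
    if n == 0 or (row > 0).sum() < 2 or (col > 0).sum() < 2:
        raise ValueError("GC2 undefined: need at least 2 non-empty rows and columns")
    expected = np.outer(row, col) / n
    mask = expected > 0
    chi2 = (((cm - expected) ** 2)[mask] / expected[mask]).sum()
    return float(chi2 / (n * (K_CLASSES - 1)))


def overall_accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    return float(np.trace(cm) / cm.sum())


@dataclass
class MetricsReport:
    """Per-class Sn/Sp/MCC, overall accuracy and GC^2 for one evaluation."""

    confusion_matrix: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    gc2: float
    folds: list["MetricsReport"] | None = None

    def to_dict(self) -> dict:
        return {
            "classes": list(CLASSES),
            "confusion": self.confusion_matrix.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "gc2": self.gc2,
        }


def report_from_confusion(cm: np.ndarray, folds=None) -> MetricsReport:
    per_class = {}
    for cls in CLASSES:
        sn, sp, mcc = class_metrics(cm, cls)
        per_class[cls] = {"sn": sn, "sp": sp, "mcc": mcc}
    try:
        g = gc2(cm)
    except ValueError:
        g = float("nan")
    return MetricsReport(np.asarray(cm), per_class, overall_accuracy(cm), g, folds)


def _train_predict(
    train_ds: DomainDataset,
    test_ds: DomainDataset,
    target_params: TargetParams | None,
    n_features: int | None,
) -> list[str]:
    results = StructuralClassModel(train_ds, target_params, n_features).fit()
    return [decide(v) for v in results.predict_vector(test_ds.X)]


def cross_validate(
    dataset: DomainDataset,
    k_folds: int = 10,
    seed: int = 1,
    target_params: TargetParams | None = None,
    n_features: int | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation, pooled over held-out folds."""
    if dataset.labels is None or dataset.ss is None:
        raise ValueError("cross-validation needs labels and secondary structure")
    labels = np.array(dataset.labels)
    counts = {c: int((labels == c).sum()) for c in CLASSES}
    small = [c for c, n in counts.items() if n < k_folds]
    if small:
        raise ValueError(
            f"classes with fewer than {k_folds} members cannot be stratified: {small}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pooled = np.zeros((K_CLASSES, K_CLASSES), dtype=int)
    fold_reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(dataset)), labels):
        pred = _train_predict(
            dataset.subset(train_idx), dataset.subset(test_idx),
            target_params, n_features,
        )
        cm = confusion(labels[test_idx], pred)
        pooled += cm
        fold_reports.append(report_from_confusion(cm))
    return report_from_confusion(pooled, folds=fold_reports)


def jackknife(
    dataset: DomainDataset,
    target_params: TargetParams | None = None,
    n_features: int | None = None,
) -> MetricsReport:
    """Leave-one-out: each domain is predicted by a model trained on the rest."""
    if dataset.labels is None or dataset.ss is None:
        raise ValueError("jackknife needs labels and secondary structure")
    n = len(dataset)
    labels = np.array(dataset.labels)
    for c in CLASSES:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} needs at least 2 members for leave-one-out")
    predictions = []
    for i in range(n):
        train_idx = np.r_[0:i, i + 1:n]
        pred = _train_predict(
            dataset.subset(train_idx), dataset.subset([i]),
            target_params, n_features,
        )
        predictions.append(pred[0])
    return report_from_confusion(confusion(labels, predictions))
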