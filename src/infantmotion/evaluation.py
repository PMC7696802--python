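"""Per-class classification metrics and unsupervised matching accuracy.

Metrics follow the usual one-vs-rest decomposition of a 4x4 confusion
matrix: precision, recall (sensitivity), specificity, balanced accuracy
= (recall + specificity)/2, and F1 = 2PR/(P+R). Macro averages are
unweighted over classes, with the population standard deviation.

Because clustering yields arbitrary cluster indices, accuracy against
ground truth is measured after the cluster-to-class assignment that
maximizes agreement (Hungarian matching on the contingency table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

N_CLASSES = 4


def confusion(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label lengths differ: {t.shape} vs {p.shape}")
    for name, arr in (("true", t), ("predicted", p)):
        bad = (arr < 0) | (arr >= n_classes)
        if bad.any():
            raise ValueError(f"unknown {name} code {arr[bad][0]}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def balanced_accuracy(recall: float, specificity: float) -> float:
    return (recall + specificity) / 2.0


@dataclass
class ClassMetrics:
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    balanced_accuracy: np.ndarray
    f1: np.ndarray
    support: np.ndarray

    def macro(self) -> dict[str, tuple[float, float]]:
        """Unweighted (mean, population s.d.) per metric over defined classes."""
        out = {}
        for name in ("precision", "recall", "specificity", "balanced_accuracy", "f1"):
            vals = getattr(self, name)
            vals = vals[~np.isnan(vals)]
            out[name] = (float(vals.mean()), float(vals.std()))
        return out

    def as_dict(self) -> dict:
        per_class = {
            name: [None if math.isnan(v) else float(v) for v in getattr(self, name)]
            for name in ("precision", "recall", "specificity", "balanced_accuracy", "f1")
        }
        per_class["support"] = self.support.tolist()
        return {"per_class": per_class,
                "macro": {k: {"mean": m, "std": s} for k, (m, s) in self.macro().items()}}


def class_metrics(cm: np.ndarray) -> ClassMetrics:
    """One-vs-rest metrics per class from a confusion matrix.

    A class with zero support (or an undefined ratio) yields NaN rather
    than a silent zero.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return np.where(den > 0, r, np.nan)

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    bal_acc = (recall + specificity) / 2.0
    f1 = ratio(2 * precision * recall, precision + recall)
    return ClassMetrics(
        precision=precision, recall=recall, specificity=specificity,
        balanced_accuracy=bal_acc, f1=f1, support=cm.sum(axis=1).astype(int),
    )


def matched_accuracy(
    true_labels, cluster_assignments, n_classes: int = N_CLASSES
) -> tuple[float, dict[int, int]]:
    """Accuracy under the best injective cluster -> class assignment.

    Maximizes the agreement count over all injective maps via the
    assignment problem on the contingency table; invariant to any
    relabeling of the clusters. When there are more clusters than
    classes the extra clusters stay unmatched (their segments count as
    errors) and a warning is attached implicitly through the partial map.
    """
    t = np.asarray(true_labels, dtype=int)
    c = np.asarray(cluster_assignments, dtype=int)
    if t.shape != c.shape:
        raise ValueError("label sequences must have equal length")
    clusters = np.unique(c)
    cont = np.zeros((clusters.size, n_classes))
    for i, cl in enumerate(clusters):
        for j in range(n_classes):
            cont[i, j] = np.sum((c == cl) & (t == j))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(clusters[i]): int(j) for i, j in zip(rows, cols)}
    correct = sum(cont[i, j] for i, j in zip(rows, cols))
    return float(correct / t.size), mapping
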