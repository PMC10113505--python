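"""One-vs-rest confusion aggregation and the classification metric suite.

Multiclass results are pooled one-vs-rest: each (sample, class) pair
contributes one binary outcome, so ``TP + TN + FP + FN`` equals
``n_samples * n_classes`` under argmax prediction.  From the pooled counts
the closed-form metrics follow:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    IoU         = TP / (TP + FP + FN)     (Jaccard)

AUC is the macro one-vs-rest rank statistic and cosine similarity is the
mean per-sample cosine between the one-hot truth and the probability row.
Percentages are rounded half-up at two decimals for display; full
precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "aggregate_confusion",
    "compute_metrics",
    "compute_curve_metrics",
    "full_report",
    "percent",
]


def percent(fraction: Optional[float], decimals: int = 2) -> Optional[float]:
    """Fraction -> percentage rounded half-up at ``decimals`` places."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled one-vs-rest TP/TN/FP/FN."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Metric values as fractions in [0, 1]; ``None`` marks an undefined
    metric (zero denominator), which is reported as absent, never as 0."""

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    f1: Optional[float] = None
    auc: Optional[float] = None
    iou: Optional[float] = None
    cosine_similarity: Optional[float] = None

    def as_percentages(self, decimals: int = 2) -> dict:
        return {
            f.name: percent(getattr(self, f.name), decimals) for f in fields(self)
        }


def _validate_scores(true_labels, predicted_scores):
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_scores, dtype=float)
    if p.ndim != 2:
        raise ValueError("predicted_scores must be (n_samples, n_classes) rows")
    if len(y) != p.shape[0]:
        raise ValueError("true_labels and predicted_scores are not parallel")
    if y.min() < 0 or y.max() >= p.shape[1]:
        raise ValueError("labels must index the score columns")
    return y, p


def aggregate_confusion(
    true_labels, predicted_scores, mode: str = "argmax"
) -> ConfusionCounts:
    """Pool binary outcomes over every (sample, class) pair.

    ``argmax`` predicts exactly one class per sample (the score maximum);
    ``threshold-0.5`` predicts class c wherever its score exceeds 0.5,
    which may predict zero or several classes per sample (and is the only
    pooling under which FP can differ from FN).
    """
    y, p = _validate_scores(true_labels, predicted_scores)
    n, c = p.shape
    truth = np.zeros((n, c), dtype=bool)
    truth[np.arange(n), y] = True
    if mode == "argmax":
        pred = np.zeros((n, c), dtype=bool)
        pred[np.arange(n), np.argmax(p, axis=1)] = True
    elif mode == "threshold-0.5":
        pred = p > 0.5
    else:
        raise ValueError("mode must be 'argmax' or 'threshold-0.5'")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cm: ConfusionCounts) -> MetricReport:
    """Closed-form metrics from pooled counts; zero-denominator metrics are
    reported as absent."""

    def ratio(num, den):
        return num / den if den > 0 else None

    return MetricReport(
        accuracy=ratio(cm.tp + cm.tn, cm.total),
        precision=ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        f1=ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        iou=ratio(cm.tp, cm.tp + cm.fp + cm.fn),
    )


def compute_curve_metrics(true_labels, predicted_scores) -> MetricReport:
    """AUC (macro one-vs-rest), IoU (from argmax counts) and mean cosine
    similarity between one-hot truth and probability rows."""
    y, p = _validate_scores(true_labels, predicted_scores)
    n, c = p.shape
    present = np.unique(y)
    if len(present) < 2:
        auc = None
    elif len(present) == c:
        if c == 2:
            auc = float(roc_auc_score(y, p[:, 1]))
        else:
            auc = float(roc_auc_score(y, p, multi_class="ovr", average="macro"))
    else:
        # macro average over classes with both positives and negatives
        aucs = []
        for k in present:
            yk = (y == k).astype(int)
            if 0 < yk.sum() < n:
                aucs.append(roc_auc_score(yk, p[:, k]))
        auc = float(np.mean(aucs)) if aucs else None
    cm = aggregate_confusion(y, p, mode="argmax")
    iou = cm.tp / (cm.tp + cm.fp + cm.fn) if (cm.tp + cm.fp + cm.fn) > 0 else None
    truth = np.zeros((n, c))
    truth[np.arange(n), y] = 1.0
    norms = np.linalg.norm(p, axis=1) * np.linalg.norm(truth, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norms > 0, (p * truth).sum(axis=1) / norms, 0.0)
    return MetricReport(auc=auc, iou=iou, cosine_similarity=float(cos.mean()))


def full_report(true_labels, predicted_scores, mode: str = "argmax") -> MetricReport:
    """Combine the closed-form and curve metrics into one report."""
    cm = aggregate_confusion(true_labels, predicted_scores, mode=mode)
    base = compute_metrics(cm)
    curve = compute_curve_metrics(true_labels, predicted_scores)
    return MetricReport(
        accuracy=base.accuracy,
        precision=base.precision,
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        f1=base.f1,
        auc=curve.auc,
        iou=curve.iou,
        cosine_similarity=curve.cosine_similarity,
    )
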