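"""Binary-classification evaluation: confusion counts, Acc/p/r/F1, ROC/AUC.

The positive class is the "normal" seed (label 1); accuracy, precision,
recall and F1 follow the usual confusion-matrix definitions, with zero
denominators reported as NaN plus an explicit flag rather than silently
coerced to zero.  The ROC curve is built by sweeping a threshold over the
unique scores (ties grouped into one step) and the AUC is the trapezoidal
area, which equals the normalized Mann–Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion",
           "metrics_from_counts", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    auc: float = float("nan")
    roc: list = field(default_factory=list)   # (fpr, tpr) points
    undefined: list = field(default_factory=list)


def confusion(predicted, actual) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual labels differ in length")
    values = set(np.unique(predicted)) | set(np.unique(actual))
    if not values <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(values)}")
    tp = int(np.sum((predicted == 1) & (actual == 1)))
    tn = int(np.sum((predicted == 0) & (actual == 0)))
    fp = int(np.sum((predicted == 1) & (actual == 0)))
    fn = int(np.sum((predicted == 0) & (actual == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics_from_counts(counts: ConfusionCounts) -> MetricReport:
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    rep = MetricReport()
    rep.accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp > 0:
        rep.precision = counts.tp / (counts.tp + counts.fp)
    else:
        rep.undefined.append("precision")
    if counts.tp + counts.fn > 0:
        rep.recall = counts.tp / (counts.tp + counts.fn)
    else:
        rep.undefined.append("recall")
    p, r = rep.precision, rep.recall
    if np.isfinite(p) and np.isfinite(r) and p + r > 0:
        rep.f1 = 2 * p * r / (p + r)
    else:
        rep.undefined.append("f1")
    return rep


def roc_auc(scores, actual) -> MetricReport:
    """ROC by threshold sweep over unique scores; AUC by the trapezoidal rule."""
    scores = np.asarray(scores, dtype=np.float64)
    actual = np.asarray(actual)
    pos = int(np.sum(actual == 1))
    neg = int(np.sum(actual == 0))
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_actual = actual[order]
    tps = np.cumsum(sorted_actual == 1)
    fps = np.cumsum(sorted_actual == 0)
    # group tied scores into a single threshold step
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / pos]
    fpr = np.r_[0.0, fps[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    rep = MetricReport(auc=auc, roc=list(zip(fpr.tolist(), tpr.tolist())))
    return rep
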