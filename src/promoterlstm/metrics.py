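"""Binary-classifier evaluation: threshold metrics and ranking curves.

Threshold metrics from the confusion counts:

    BA  = (SN + SP) / 2
    SN  = TP / (TP + FN)          SP = TN / (TN + FP)
    PR  = TP / (TP + FP)          F1 = 2 * PR * SN / (PR + SN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero denominators return 0 (a documented sentinel that keeps every
metric inside its nominal range).  The ROC area uses trapezoidal
integration over the full threshold sweep, which equals the pairwise
concordance probability with half credit for ties; the PR area uses the
interpolation-free step rule (sum of precision times recall increment),
so a constant score degenerates to the prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np


class MetricUndefinedError(ValueError):
    """A curve metric was requested for input lacking a required class."""


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts at one decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdMetrics:
    ba: float
    sn: float
    sp: float
    pr: float
    f1: float
    mcc: float


@dataclass
class EvalReport:
    """Full evaluation at one threshold plus threshold-free curve areas."""

    counts: ConfusionCounts
    ba: float
    sn: float
    sp: float
    pr: float
    f1: float
    mcc: float
    aucroc: float
    aucpr: float
    threshold: float
    roc_points: List[Tuple[float, float]] = field(default_factory=list)
    pr_points: List[Tuple[float, float]] = field(default_factory=list)

    def as_dict(self, ndigits: int = 2) -> Dict[str, object]:
        """Report dictionary with metrics rounded for display."""
        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
            "threshold": self.threshold,
            **{
                name: round(getattr(self, name), ndigits)
                for name in ("ba", "sn", "sp", "pr", "f1", "mcc", "aucroc", "aucpr")
            },
        }


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1")
    return arr.astype(np.int64)


def confusion(labels, predictions) -> ConfusionCounts:
    """Confusion counts for binary labels and binary predictions."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def threshold_metrics(counts: ConfusionCounts) -> ThresholdMetrics:
    """The six threshold metrics from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    pr = _ratio(tp, tp + fp)
    f1 = _ratio(2.0 * pr * sn, pr + sn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return ThresholdMetrics(ba=(sn + sp) / 2.0, sn=sn, sp=sp, pr=pr, f1=f1, mcc=mcc)


def _sweep(labels, scores) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Cumulative tp/fp after each distinct score threshold (descending)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    # indices where a threshold group (tied scores) ends
    distinct = np.flatnonzero(np.diff(s)) if s.size else np.array([], dtype=int)
    ends = np.r_[distinct, s.size - 1] if s.size else np.array([], dtype=int)
    tps = np.cumsum(y)[ends]
    fps = np.cumsum(1 - y)[ends]
    return tps, fps, int(y.sum()), int((1 - y).sum())


def roc_curve_and_area(labels, scores) -> Tuple[List[Tuple[float, float]], float]:
    """ROC points over all distinct thresholds and the trapezoidal area.

    Equals the tie-corrected rank (concordance) statistic.  Requires both
    classes to be present.
    """
    tps, fps, n_pos, n_neg = _sweep(labels, scores)
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("ROC requires both classes present")
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    area = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), area


def pr_curve_and_area(labels, scores) -> Tuple[List[Tuple[float, float]], float]:
    """Precision-recall points and the step-rule area (average precision).

    Area = sum over the descending-threshold sweep of
    ``precision_i * (recall_i - recall_{i-1})``.  Requires at least one
    positive.
    """
    tps, fps, n_pos, _ = _sweep(labels, scores)
    if n_pos == 0:
        raise MetricUndefinedError("PR curve requires at least one positive")
    recall = tps / n_pos
    precision = tps / np.maximum(tps + fps, 1)
    d_recall = np.diff(np.r_[0.0, recall])
    area = float(np.sum(precision * d_recall))
    points = list(zip(recall.tolist(), precision.tolist()))
    return points, area


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion at the threshold, six metrics, both areas."""
    scores = np.asarray(scores, dtype=np.float64)
    preds = (scores >= threshold).astype(np.int64)
    counts = confusion(labels, preds)
    tm = threshold_metrics(counts)
    roc_points, aucroc = roc_curve_and_area(labels, scores)
    pr_points, aucpr = pr_curve_and_area(labels, scores)
    return EvalReport(
        counts=counts,
        ba=tm.ba,
        sn=tm.sn,
        sp=tm.sp,
        pr=tm.pr,
        f1=tm.f1,
        mcc=tm.mcc,
        aucroc=aucroc,
        aucpr=aucpr,
        threshold=threshold,
        roc_points=roc_points,
        pr_points=pr_points,
    )
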