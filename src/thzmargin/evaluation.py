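"""Pixelwise diagnostic evaluation against the registered reference mask.

Confusion counts, TPR/FPR, threshold-swept ROC curves per structuring
element, trapezoidal AUC, and best-threshold selection by the TPR − FPR
criterion.  The reference (pathologist) mask defines the positives; on
disagreement it always prevails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError, ValidationError
from .inversion import IndexMap
from .segmentation import StructuringElement, dilate, threshold_map

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ROCPoint",
    "ROCCurve",
    "default_thresholds",
    "evaluable_mask",
    "confusion",
    "tpr",
    "fpr",
    "specificity",
    "roc_curve",
    "auc",
    "best_thresholds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    tpr: float
    fpr: float
    counts: ConfusionCounts | None = None

    @property
    def youden(self) -> float:
        return self.tpr - self.fpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


@dataclass
class ROCCurve:
    """Per-threshold operating points for one structuring-element rank."""

    points: list
    classifier_rank: int = 0

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.threshold)
        for p in self.points:
            if not (0.0 <= p.tpr <= 1.0 and 0.0 <= p.fpr <= 1.0):
                raise ValidationError("tpr and fpr must lie in [0, 1]")


def default_thresholds(step: float = 0.1, n_min: float = 1.5,
                       n_max: float = 3.0) -> np.ndarray:
    count = int(round((n_max - n_min) / step)) + 1
    return np.round(np.linspace(n_min, n_max, count), 10)


def evaluable_mask(pred_support: np.ndarray, truth_support: np.ndarray) -> np.ndarray:
    """Pixels where both classifications carry tissue; all others are
    "not applicable" and excluded from counting."""
    pred_support = np.asarray(pred_support, dtype=bool)
    truth_support = np.asarray(truth_support, dtype=bool)
    if pred_support.shape != truth_support.shape:
        raise ValidationError("supports must share one shape")
    return pred_support & truth_support


def confusion(pred: np.ndarray, truth: np.ndarray,
              evaluable: np.ndarray) -> ConfusionCounts:
    """Confusion counts over the evaluable region; truth defines positives."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    evaluable = np.asarray(evaluable, dtype=bool)
    if not (pred.shape == truth.shape == evaluable.shape):
        raise ValidationError("pred, truth and evaluable must share one shape")
    if not evaluable.any():
        raise EvaluationError('empty evaluable region ("not applicable" everywhere)')
    p = pred[evaluable]
    t = truth[evaluable]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def tpr(c: ConfusionCounts) -> float:
    """Sensitivity: tp / (tp + fn)."""
    den = c.tp + c.fn
    if den == 0:
        raise EvaluationError("TPR undefined: no positive pixels in the reference")
    return c.tp / den


def fpr(c: ConfusionCounts) -> float:
    """1 − specificity: fp / (fp + tn)."""
    den = c.fp + c.tn
    if den == 0:
        raise EvaluationError("FPR undefined: no negative pixels in the reference")
    return c.fp / den


def specificity(c: ConfusionCounts) -> float:
    return 1.0 - fpr(c)


def roc_curve(index_map: IndexMap, truth: np.ndarray, evaluable: np.ndarray,
              se: StructuringElement, thresholds,
              support: np.ndarray | None = None) -> ROCCurve:
    """ROC for one structuring element: threshold → one constrained dilation
    → confusion → (tpr, fpr) per threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("thresholds must be non-empty")
    if support is None:
        support = index_map.support
    points = []
    for t in thresholds:
        try:
            pred = dilate(threshold_map(index_map, float(t)), se, support)
            c = confusion(pred, truth, evaluable)
            points.append(ROCPoint(threshold=float(t), tpr=tpr(c), fpr=fpr(c),
                                   counts=c))
        except EvaluationError as exc:
            raise EvaluationError(f"threshold {t:g}: {exc}") from exc
    return ROCCurve(points=points, classifier_rank=se.rank)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve, anchored at (0,0) and (1,1).

    Points are sorted by FPR internally (dilated curves need not be monotone
    in threshold), so the result is invariant to point ordering.
    """
    if len(curve.points) < 2:
        raise ValidationError("AUC requires at least 2 points")
    pairs = sorted(((p.fpr, p.tpr) for p in curve.points))
    xs = np.array([0.0] + [f for f, _ in pairs] + [1.0])
    ys = np.array([0.0] + [t for _, t in pairs] + [1.0])
    return float(np.trapezoid(ys, xs))


def best_thresholds(curve: ROCCurve, k: int = 2) -> list:
    """Top-k operating points by TPR − FPR, descending.

    Ties resolve to the higher specificity (lower FPR), then the lower
    threshold.  When k exceeds the curve length all points are returned and
    the shortfall is logged.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranked = sorted(curve.points, key=lambda p: (-p.youden, p.fpr, p.threshold))
    if k > len(ranked):
        logger.warning("best_thresholds: k=%d exceeds curve length %d; returning all",
                       k, len(ranked))
        return ranked
    return ranked[:k]
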