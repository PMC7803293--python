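"""Pixel-classification evaluation restricted to the field of view.

Vessel segmentation is scored as binary pixel classification against the
expert annotation, counting only pixels inside the FOV mask (the standard
DRIVE/STARE protocol; pass ``fov=None`` to score the whole frame):

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)          (true-positive rate on vessels)
    specificity = TN / (TN + FP)          (true-negative rate on background)
    precision   = TP / (TP + FP)
    F           = 2 * precision * sensitivity / (precision + sensitivity)

ROC/AUC sweeps the binarization threshold over the unique probability
values and integrates sensitivity against (1 - specificity) with the
trapezoidal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies over the evaluated (in-FOV) region."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Derived metrics; a metric with zero denominator is reported as NaN."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_measure: float
    auc: float | None = None


def confusion(pred: np.ndarray, truth: np.ndarray,
              fov: np.ndarray | None = None) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between binary prediction and truth inside the FOV."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise InvalidInputError(
            f"prediction {pred.shape} and truth {truth.shape} shapes differ")
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != pred.shape:
            raise InvalidInputError(
                f"fov {fov.shape} does not match prediction {pred.shape}")
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> MetricReport:
    """Sensitivity, specificity, accuracy, precision and F-measure."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated pixels: all counts are zero")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    prec = _ratio(c.tp, c.tp + c.fp)
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f = float("nan")
    else:
        f = 2.0 * prec * sens / (prec + sens)
    return MetricReport(sensitivity=sens, specificity=spec, accuracy=acc,
                        precision=prec, f_measure=f)


def roc_auc(prob: np.ndarray, truth: np.ndarray,
            fov: np.ndarray | None = None,
            n_thresholds: int | None = None):
    """Area under the ROC curve plus the curve itself.

    Sweeps every unique probability value as a threshold (or
    ``n_thresholds`` uniform thresholds in [0, 1] if given) and returns
    ``(auc, points)`` where points is an array of (1 - specificity,
    sensitivity) pairs sorted by false-positive rate, including (0, 0)
    and (1, 1).
    """
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if prob.shape != truth.shape:
        raise InvalidInputError(
            f"probability {prob.shape} and truth {truth.shape} shapes differ")
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        prob, truth = prob[fov], truth[fov]
    prob, truth = prob.ravel(), truth.ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("truth must contain both classes for ROC")
    if n_thresholds is None:
        thresholds = np.unique(prob)
    else:
        thresholds = np.linspace(0.0, 1.0, int(n_thresholds))
    # vectorized sweep via sorting: for threshold t, TP = #(prob >= t & pos)
    order = np.argsort(prob, kind="stable")
    sorted_prob = prob[order]
    pos_cum = np.cumsum(truth[order][::-1])[::-1]        # positives with rank >= i
    neg_cum = np.cumsum((~truth)[order][::-1])[::-1]
    idx = np.searchsorted(sorted_prob, thresholds, side="left")
    tp = np.where(idx < prob.size, pos_cum[np.minimum(idx, prob.size - 1)], 0)
    fp = np.where(idx < prob.size, neg_cum[np.minimum(idx, prob.size - 1)], 0)
    tpr = tp / n_pos
    fpr = fp / n_neg
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return auc, pts
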