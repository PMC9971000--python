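"""Segmentation-overlap and TMH-agreement metrics.

Overlap between a predicted and a labelled binary mask is summarised by the
standard confusion counts and derived from them: IoU (Jaccard),
Dice (F1), and sensitivity (recall, TP / (TP + FN)); precision is reported
alongside.  Class-mean variants average the background and target classes
without weighting.  Agreement between automated and manual TMH readings uses
ordinary least squares (true value regressed on the predicted value, matching
the axis convention of the method's evaluation plots) and the two-way random,
absolute-agreement, single-measures intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InputError

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "RegressionFit",
    "ICCResult",
    "confusion",
    "iou",
    "dice",
    "sensitivity",
    "precision",
    "seg_metrics",
    "tmh_regression",
    "icc_agreement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts for one binary mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_matrix(self) -> np.ndarray:
        """2×2 matrix, rows = truth (bg, target), cols = prediction."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)


@dataclass(frozen=True)
class SegMetrics:
    """Per-class and class-mean overlap metrics (index 0 = background,
    index 1 = target)."""

    iou_per_class: tuple[float, float]
    dice_per_class: tuple[float, float]
    sensitivity_per_class: tuple[float, float]
    precision_per_class: tuple[float, float]

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.iou_per_class))

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.dice_per_class))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity_per_class))


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of true TMH on predicted TMH."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation between two TMH raters."""

    icc: float
    variant: str = "ICC(2,1) two-way random, absolute agreement, single measures"


def _binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise InputError(f"{name} must be binary with values in {{0, 1}}")
        arr = arr.astype(bool)
    return arr


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between prediction and label."""
    pred = _binary(pred_mask, "pred_mask")
    true = _binary(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise InputError(
            f"shape mismatch: pred {pred.shape} vs true {true.shape}"
        )
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union; 1.0 by convention when both masks are empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient; 1.0 by convention when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """Recall, TP / (TP + FN). Undefined (error) without ground-truth target."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise InputError("sensitivity undefined: ground truth has no target pixels")
    return counts.tp / denom


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP). Undefined (error) when nothing is predicted."""
    denom = counts.tp + counts.fp
    if denom == 0:
        raise InputError("precision undefined: prediction has no target pixels")
    return counts.tp / denom


def _flip(c: ConfusionCounts) -> ConfusionCounts:
    """Confusion counts with the class roles swapped (background as target)."""
    return ConfusionCounts(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp)


def seg_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> SegMetrics:
    """Per-class IoU/Dice/sensitivity/precision and their unweighted means.

    Sensitivity/precision entries that are undefined for a class (no
    ground-truth pixels / no predicted pixels of that class) are reported as
    NaN rather than raising, so a degenerate prediction can still be scored.
    """
    c1 = confusion(pred_mask, true_mask)
    c0 = _flip(c1)

    def _safe(fn, c):
        try:
            return fn(c)
        except InputError:
            return float("nan")

    return SegMetrics(
        iou_per_class=(iou(c0), iou(c1)),
        dice_per_class=(dice(c0), dice(c1)),
        sensitivity_per_class=(_safe(sensitivity, c0), _safe(sensitivity, c1)),
        precision_per_class=(_safe(precision, c0), _safe(precision, c1)),
    )


def _paired(true_tmh, pred_tmh, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_tmh, dtype=np.float64).ravel()
    p = np.asarray(pred_tmh, dtype=np.float64).ravel()
    if t.shape != p.shape:
        raise InputError("true and predicted TMH lists must have equal length")
    if t.size < min_n:
        raise InputError(f"need at least {min_n} paired values, got {t.size}")
    return t, p


def tmh_regression(true_tmh, pred_tmh) -> RegressionFit:
    """OLS regression of true TMH (ordinate) on predicted TMH (abscissa)."""
    t, p = _paired(true_tmh, pred_tmh, min_n=3)
    if np.ptp(p) == 0:
        raise DegenerateFitError("predicted TMH has zero variance")
    res = stats.linregress(p, t)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=t.size,
    )


def icc_agreement(true_tmh, pred_tmh) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the n×2 rating table
    (subjects × raters)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the residual
    mean square, k = 2 raters.
    """
    t, p = _paired(true_tmh, pred_tmh, min_n=3)
    x = np.column_stack([t, p])  # n subjects × k raters
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        raise DegenerateFitError("constant ratings: ICC undefined")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    resid = x - subj_means[:, None] - rater_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise DegenerateFitError("degenerate variance decomposition")
    return ICCResult(icc=float((msr - mse) / denom))
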