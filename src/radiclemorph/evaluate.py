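"""Detection/segmentation evaluation arithmetic and agreement analysis.

Covers the standard instance-detection metrics — average precision at a
single IoU threshold and its mean over IoU 0.50:0.05:0.95 — plus the
convolution complexity formulas

    FLOPS  = 2 * H * W * (C_in * K^2 + 1) * C_out
    Params = C_in * K^2 * C_out

(exact integer arithmetic; the +1 accounts for the bias add), and the
machine-vs-manual length agreement analysis: ordinary least squares of
machine-measured length on manual length, with R^2 and per-series
summary statistics.

AP uses greedy matching in descending confidence (each ground truth
consumable once) and all-points interpolation: the precision envelope
is made monotone from the right before integrating, which evaluates the
continuous integral of P(R) exactly for finite data. Users comparing to
COCO-style 101-point sampling should expect small differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DetectionRecord",
    "EvalResult",
    "ComplexityReport",
    "AgreementReport",
    "box_iou",
    "mask_iou",
    "average_precision",
    "map_range",
    "conv_complexity",
    "agreement_analysis",
]

MAP_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass
class DetectionRecord:
    """One prediction or ground truth: half-open continuous box
    (x_min, y_min, x_max, y_max), confidence, optional binary mask."""

    box: tuple[float, float, float, float]
    confidence: float = 1.0
    mask: np.ndarray | None = None
    class_id: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class EvalResult:
    per_threshold_ap: dict[float, float]
    map50: float
    map50_95: float
    n_classes: int
    precision_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    recall_curve: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class ComplexityReport:
    H: int
    W: int
    C_in: int
    C_out: int
    K: int
    flops: int
    params: int


@dataclass
class AgreementReport:
    slope: float
    intercept: float
    r_squared: float
    machine_stats: dict[str, float]
    manual_stats: dict[str, float]


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection over union of two half-open boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if not (ax0 < ax1 and ay0 < ay1) or not (bx0 < bx1 and by0 < by1):
        raise ValueError(f"degenerate box in IoU: {a} / {b}")
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of two equal-size binary masks; two empty masks give 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _pair_iou(pred: DetectionRecord, truth: DetectionRecord, use_mask: bool) -> float:
    if use_mask:
        if pred.mask is None or truth.mask is None:
            raise ValueError("mask IoU requested but a record has no mask")
        return mask_iou(pred.mask, truth.mask)
    return box_iou(pred.box, truth.box)


def _pr_curve(
    preds: Sequence[DetectionRecord],
    truths: Sequence[DetectionRecord],
    iou_threshold: float,
    use_mask: bool,
) -> tuple[np.ndarray, np.ndarray]:
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched = [False] * len(truths)
    tp = np.zeros(len(preds))
    fp = np.zeros(len(preds))
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, truth in enumerate(truths):
            if matched[j]:
                continue
            iou = _pair_iou(preds[i], truth, use_mask)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[rank] = 1
        else:
            fp[rank] = 1
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    precision = ctp / np.maximum(ctp + cfp, 1)
    recall = ctp / max(len(truths), 1)
    return precision, recall


def _ap_from_pr(precision: np.ndarray, recall: np.ndarray) -> float:
    """Area under the monotone precision envelope (all-points rule)."""
    p = np.concatenate([[0.0], precision, [0.0]])
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.nonzero(np.diff(r))[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def average_precision(
    preds: Sequence[DetectionRecord],
    truths: Sequence[DetectionRecord],
    iou_threshold: float,
    use_mask: bool = False,
) -> float:
    """AP for one class at one IoU threshold."""
    if not (0 < iou_threshold < 1):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    if not truths:
        return 0.0
    if not preds:
        return 0.0
    precision, recall = _pr_curve(preds, truths, iou_threshold, use_mask)
    return _ap_from_pr(precision, recall)


def map_range(
    preds: Sequence[DetectionRecord],
    truths: Sequence[DetectionRecord],
    use_mask: bool = False,
) -> EvalResult:
    """AP at the 10 IoU thresholds 0.50:0.05:0.95, averaged over classes
    (1/n_c) at each threshold; map50_95 is the unweighted threshold mean."""
    class_ids = sorted({t.class_id for t in truths}) or [0]
    per_threshold: dict[float, float] = {}
    for thr in MAP_THRESHOLDS:
        aps = []
        for cid in class_ids:
            p = [d for d in preds if d.class_id == cid]
            t = [d for d in truths if d.class_id == cid]
            aps.append(average_precision(p, t, thr, use_mask=use_mask))
        per_threshold[thr] = float(np.mean(aps))
    pr_p, pr_r = (
        _pr_curve(preds, truths, 0.5, use_mask) if preds and truths else (np.empty(0), np.empty(0))
    )
    return EvalResult(
        per_threshold_ap=per_threshold,
        map50=per_threshold[0.5],
        map50_95=float(np.mean(list(per_threshold.values()))),
        n_classes=len(class_ids),
        precision_curve=pr_p,
        recall_curve=pr_r,
    )


def conv_complexity(H: int, W: int, C_in: int, K: int, C_out: int) -> ComplexityReport:
    """Convolution layer cost: exact integers, no floating point."""
    for name, v in (("H", H), ("W", W), ("C_in", C_in), ("K", K), ("C_out", C_out)):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    flops = 2 * H * W * (C_in * K * K + 1) * C_out
    params = C_in * K * K * C_out
    return ComplexityReport(H=H, W=W, C_in=C_in, C_out=C_out, K=K, flops=flops, params=params)


def _series_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def agreement_analysis(machine_cm: Sequence[float], manual_cm: Sequence[float]) -> AgreementReport:
    """OLS of machine length (y) on manual length (x), closed form.

    slope = cov(x, y) / var(x); r_squared = 1 - SS_res / SS_tot. Raises
    if the series differ in length, contain non-finite values, or x has
    zero variance.
    """
    y = np.asarray(machine_cm, dtype=float)
    x = np.asarray(manual_cm, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("machine and manual series must be equal-length 1-D with >= 2 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("manual series has zero variance; regression undefined")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - ym) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        machine_stats=_series_stats(y),
        manual_stats=_series_stats(x),
    )
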