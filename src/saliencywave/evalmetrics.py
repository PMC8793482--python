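"""Threshold-sweep evaluation of saliency maps against binary GT.

Saliency maps are quantized to 8 bits and binarized at every threshold
tau in 0..255 (strict inequality ``map8 > tau``); confusion counts per
threshold yield precision-recall and ROC curves, with ROC-AUC computed
by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalCurve",
    "quantize_map",
    "confusion_at_threshold",
    "pr_curve",
    "roc_curve",
    "curve_auc",
    "mean_roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvalCurve:
    """Ordered (x, y) curve points with trapezoid AUC."""

    x: np.ndarray
    y: np.ndarray
    kind: str  # "pr" or "roc"
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


def quantize_map(saliency_map: np.ndarray) -> np.ndarray:
    """Round a [0, 1] map to 8-bit levels."""
    saliency_map = np.asarray(saliency_map, dtype=float)
    return np.rint(np.clip(saliency_map, 0.0, 1.0) * 255.0).astype(np.uint8)


def _check_pair(saliency_map: np.ndarray, gt_mask: np.ndarray):
    saliency_map = np.asarray(saliency_map)
    gt_mask = np.asarray(gt_mask).astype(bool)
    if saliency_map.shape != gt_mask.shape:
        raise ValueError(
            f"shape mismatch: map {saliency_map.shape} vs GT {gt_mask.shape}"
        )
    if saliency_map.dtype != np.uint8:
        saliency_map = quantize_map(saliency_map)
    return saliency_map, gt_mask


def confusion_at_threshold(
    saliency_map: np.ndarray, gt_mask: np.ndarray, tau: int
) -> ConfusionCounts:
    """Pixel confusion counts of ``map8 > tau`` against the GT mask."""
    map8, gt = _check_pair(saliency_map, gt_mask)
    binary = map8 > tau
    tp = int(np.count_nonzero(binary & gt))
    fp = int(np.count_nonzero(binary & ~gt))
    fn = int(np.count_nonzero(~binary & gt))
    tn = int(np.count_nonzero(~binary & ~gt))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _cumulative_counts(map8: np.ndarray, gt: np.ndarray):
    # TP(tau) = #{positive pixels with value > tau}; via reversed cumsum of
    # the 256-bin histograms of positive and negative pixels.
    pos_hist = np.bincount(map8[gt].ravel(), minlength=256)
    neg_hist = np.bincount(map8[~gt].ravel(), minlength=256)
    # counts strictly above tau for tau = 0..255
    tp = pos_hist[::-1].cumsum()[::-1]
    fp = neg_hist[::-1].cumsum()[::-1]
    tp = np.concatenate([tp[1:], [0]])
    fp = np.concatenate([fp[1:], [0]])
    return tp.astype(float), fp.astype(float), pos_hist.sum(), neg_hist.sum()


def pr_curve(saliency_map: np.ndarray, gt_mask: np.ndarray) -> EvalCurve:
    """Precision-recall curve over thresholds 0..255.

    Precision at thresholds with no predicted positives is defined as 1.
    """
    map8, gt = _check_pair(saliency_map, gt_mask)
    tp, fp, n_pos, _ = _cumulative_counts(map8, gt)
    if n_pos == 0:
        raise ValueError("GT mask has no positive pixels; recall undefined")
    recall = tp / n_pos
    predicted = tp + fp
    precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 1.0)
    order = np.argsort(recall, kind="stable")
    auc = float(np.trapezoid(precision[order], recall[order]))
    return EvalCurve(x=recall, y=precision, kind="pr", auc=auc)


def roc_curve(saliency_map: np.ndarray, gt_mask: np.ndarray) -> EvalCurve:
    """ROC curve over thresholds 0..255, augmented with (0,0) and (1,1)."""
    map8, gt = _check_pair(saliency_map, gt_mask)
    tp, fp, n_pos, n_neg = _cumulative_counts(map8, gt)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("GT mask must contain both positive and negative pixels")
    tpr = np.concatenate([[1.0], tp / n_pos, [0.0]])
    fpr = np.concatenate([[1.0], fp / n_neg, [0.0]])
    auc = curve_auc(fpr, tpr)
    return EvalCurve(x=fpr, y=tpr, kind="roc", auc=auc)


def curve_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Trapezoid area under a curve after sorting by (x, y).

    The secondary y sort keeps vertical runs ascending so the polyline
    traces the ROC staircase instead of cutting across its corners.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def mean_roc_auc(pairs) -> dict:
    """Dataset summary: mean ROC-AUC over (map, gt) pairs."""
    aucs = [roc_curve(m, g).auc for m, g in pairs]
    return {"mean_auc": float(np.mean(aucs)), "n_images": len(aucs)}
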