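"""Segmentation evaluation: Hausdorff distance, Dice and Jaccard indices,
and Bland-Altman agreement of segmented areas.

Conventions: probability maps are thresholded at 0.5 upstream; Dice and
Jaccard of two empty masks are defined as 1.0; the Hausdorff distance of
an empty mask is undefined and raises.  Contours for the Hausdorff
distance are the mask pixels with at least one 4-neighbour outside the
mask, with pixel centres as coordinates, scaled by the pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class MetricRecord:
    """Per-image, per-structure segmentation scores and pixel counts."""

    structure: str
    hd: float
    di: float
    ji: float
    n_tp: int
    n_fp: int
    n_fn: int


@dataclass
class AgreementSummary:
    """Bland-Altman bias and 95% limits of agreement of segmented areas."""

    bias: float
    loa_low: float
    loa_high: float


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} is not binary")
        m = m.astype(bool)
    return m


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    """(true positive, false positive, false negative) pixel counts."""
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return tp, fp, fn


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice index 2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    tp, fp, fn = confusion_counts(pred, gt)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def jaccard(pred: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard index TP / (TP + FP + FN); 1.0 when both masks are empty."""
    tp, fp, fn = confusion_counts(pred, gt)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def contour_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of boundary pixel coordinates (row, col).

    A boundary pixel is a mask pixel with at least one 4-neighbour
    outside the mask (image-border pixels count the outside as off-mask).
    """
    m = _as_binary(mask, "mask")
    padded = np.pad(m, 1)
    inner = (padded[:-2, 1:-1] & padded[2:, 1:-1]
             & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~inner)


def hausdorff(pred: np.ndarray, gt: np.ndarray, spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between mask contours, in mm.

    max of the two directed max-min Euclidean distances between the
    contour point sets of prediction and ground truth.
    """
    p = contour_points(pred)
    g = contour_points(gt)
    if len(p) == 0 or len(g) == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    d = cdist(p.astype(np.float64), g.astype(np.float64))
    return float(spacing * max(d.min(axis=1).max(), d.min(axis=0).max()))


def evaluate_pair(pred: np.ndarray, gt: np.ndarray, structure: str,
                  spacing: float = 1.0) -> MetricRecord:
    """All three metrics for one prediction/ground-truth mask pair."""
    tp, fp, fn = confusion_counts(pred, gt)
    return MetricRecord(
        structure=structure,
        hd=hausdorff(pred, gt, spacing),
        di=dice(pred, gt),
        ji=jaccard(pred, gt),
        n_tp=tp, n_fp=fp, n_fn=fn,
    )


def bland_altman(areas_pred, areas_gt) -> AgreementSummary:
    """Bias and 95% limits of agreement between paired area measurements.

    bias = mean(pred - gt); limits = bias +/- 1.96 * sd of the
    differences (sample standard deviation, ddof=1).
    """
    ap = np.asarray(areas_pred, dtype=np.float64)
    ag = np.asarray(areas_gt, dtype=np.float64)
    if ap.shape != ag.shape:
        raise ValueError("area lists must have equal length")
    if ap.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    diff = ap - ag
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementSummary(bias=bias, loa_low=bias - 1.96 * sd,
                            loa_high=bias + 1.96 * sd)


def bland_altman_plot(areas_pred, areas_gt, ax=None, label: str = "structure"):
    """Difference-vs-mean agreement plot with bias and limit lines."""
    import matplotlib.pyplot as plt

    summary = bland_altman(areas_pred, areas_gt)
    ap = np.asarray(areas_pred, dtype=np.float64)
    ag = np.asarray(areas_gt, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((ap + ag) / 2.0, ap - ag, s=12, alpha=0.7)
    ax.axhline(summary.bias, color="forestgreen", label=f"bias {summary.bias:.2f}")
    for lim in (summary.loa_low, summary.loa_high):
        ax.axhline(lim, color="saddlebrown", linestyle="--")
    ax.set_xlabel("mean area")
    ax.set_ylabel("area difference (pred - gt)")
    ax.set_title(f"Bland-Altman: {label}")
    ax.legend()
    return ax
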