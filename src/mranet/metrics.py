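"""Segmentation evaluation suite.

Per-image overlap metrics (IoU, Dice, Recall, Precision, F2) computed from
pixel confusion counts, the exact symmetric Hausdorff distance between mask
boundaries, and unweighted dataset means of every per-image column. The F-beta
score uses beta = 2, weighting recall twice as heavily as precision. Because
every metric is averaged per image first, the reported F2 mean is generally
not the F-beta of the reported mean recall/precision.

Degenerate conventions (declared, not universal): if prediction and reference
are both empty all overlap metrics are 1 and HD is 0; if exactly one is empty
the overlap metrics are 0 and HD is the image diagonal. Boundary points are
foreground pixels with a 4-neighbour outside the mask or on the image border.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .backbone import ConfigurationError, DimensionError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "binarize",
    "confusion_counts",
    "overlap_metrics",
    "boundary_points",
    "hausdorff_distance",
    "evaluate_dataset",
]

METRIC_COLUMNS = ("iou", "dsc", "recall", "precision", "f2", "hd")
MEAN_NAMES = {"iou": "mIoU", "dsc": "mDSC", "recall": "Recall",
              "precision": "Precision", "f2": "F2", "hd": "HD"}


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    per_image: list[dict[str, float]]
    means: dict[str, float]
    n_images: int

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("image",) + METRIC_COLUMNS)
            for i, rec in enumerate(self.per_image):
                writer.writerow([i] + [rec[c] for c in METRIC_COLUMNS])
            writer.writerow(["mean"] + [self.means[MEAN_NAMES[c]]
                                        for c in METRIC_COLUMNS])

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_image": self.per_image, "means": self.means,
                       "n_images": self.n_images}, fh, indent=2)


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities; ties (exactly equal) go to the foreground."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(
            f"threshold must lie strictly in (0, 1), got {threshold}")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"{name} mask must be binary (0/1)")
    return arr.astype(bool)


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    p = _as_binary(pred_mask, "prediction")
    g = _as_binary(gt_mask, "reference")
    if p.shape != g.shape:
        raise DimensionError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(pred_mask, gt_mask) -> dict[str, float]:
    """IoU, Dice, recall, precision and F2 from pixel confusion counts."""
    c = confusion_counts(pred_mask, gt_mask)
    pred_empty = (c.tp + c.fp) == 0
    gt_empty = (c.tp + c.fn) == 0
    if pred_empty and gt_empty:
        return {k: 1.0 for k in ("iou", "dsc", "recall", "precision", "f2")}
    if pred_empty or gt_empty:
        return {k: 0.0 for k in ("iou", "dsc", "recall", "precision", "f2")}
    iou = c.tp / (c.tp + c.fp + c.fn)
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    recall = c.tp / (c.tp + c.fn)
    precision = c.tp / (c.tp + c.fp)
    beta2 = 4.0  # beta = 2
    denom = beta2 * precision + recall
    f2 = (1 + beta2) * precision * recall / denom if denom > 0 else 0.0
    return {"iou": iou, "dsc": dsc, "recall": recall,
            "precision": precision, "f2": f2}


def boundary_points(mask) -> np.ndarray:
    """(row, col) coordinates of boundary pixels of a binary mask.

    A foreground pixel is on the boundary iff at least one 4-neighbour is
    background or the pixel touches the image border.
    """
    m = _as_binary(mask, "mask")
    if m.ndim != 2:
        raise DimensionError(f"mask must be 2-D, got shape {m.shape}")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    return np.argwhere(boundary)


def hausdorff_distance(pred_mask, gt_mask) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in pixels."""
    p = np.asarray(pred_mask)
    g = np.asarray(gt_mask)
    if p.shape != g.shape:
        raise DimensionError(f"mask shapes differ: {p.shape} vs {g.shape}")
    a = boundary_points(p)
    b = boundary_points(g)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        h, w = p.shape
        return float(np.hypot(h - 1, w - 1))
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def evaluate_dataset(pred_maps, gt_masks, threshold: float = 0.5) -> MetricsReport:
    """Per-image metrics and their unweighted arithmetic means.

    ``pred_maps`` are probability maps (thresholded internally);
    ``gt_masks`` are binary reference masks.
    """
    preds = list(pred_maps)
    gts = list(gt_masks)
    if len(preds) == 0:
        raise ValueError("evaluate_dataset requires at least one image")
    if len(preds) != len(gts):
        raise ValueError(
            f"prediction/reference count mismatch: {len(preds)} vs {len(gts)}")
    per_image = []
    for pred, gt in zip(preds, gts):
        pm = binarize(np.squeeze(np.asarray(pred)), threshold)
        gm = np.squeeze(np.asarray(gt))
        rec = overlap_metrics(pm, gm)
        rec["hd"] = hausdorff_distance(pm, gm)
        per_image.append(rec)
    means = {MEAN_NAMES[c]: float(np.mean([r[c] for r in per_image]))
             for c in METRIC_COLUMNS}
    return MetricsReport(per_image=per_image, means=means,
                         n_images=len(per_image))
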