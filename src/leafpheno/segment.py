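"""Plant segmentation and pixel-level evaluation.

The reference segmenter thresholds the excess-green index (2G - R - B) with
Otsu's method and removes small spurious components.  It stands behind the
same interface any external segmenter (including a deep network's masks
loaded from disk) can use: downstream stages only consume binary masks.

Evaluation follows the standard pixel-confusion definitions

    IOU    = TP / (TP + FP + FN)
    PA     = (TP + TN) / (TP + FP + FN + TN)
    Recall = TP / (TP + FN)

with an optional ``paper_literal`` variant (IOU = TP/(TP+FP+TN),
PA = (TP+TN)/(TP+FP+TN), Recall = TP/(TP+TN)) kept for auditability of
formula transcriptions that swap FN and TN.  Empty denominators yield NaN,
never silently 0.  Dataset-level scores are per-image means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "ConfusionCounts",
    "segment",
    "excess_green",
    "confusion_counts",
    "evaluate_mask",
    "evaluate_pair",
    "apply_mask",
    "to_gray",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts between a predicted and a true binary mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def excess_green(image) -> np.ndarray:
    """Excess-green index 2G - R - B as a signed integer image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    r = image[..., 0].astype(np.int32)
    g = image[..., 1].astype(np.int32)
    b = image[..., 2].astype(np.int32)
    return 2 * g - r - b


def segment(image, method: str = "reference", min_size: int = 16) -> np.ndarray:
    """Produce a boolean plant mask from an RGB image.

    The reference method applies Otsu's threshold to the excess-green index
    and drops connected components smaller than ``min_size`` pixels.  A
    uniform image (Otsu undefined) yields an all-background mask with a
    warning.
    """
    if method != "reference":
        raise ValueError(f"unknown method {method!r}; pass external masks directly")
    exg = excess_green(image)
    if exg.min() == exg.max():
        warnings.warn("uniform image: Otsu threshold undefined, returning empty mask")
        return np.zeros(exg.shape, dtype=bool)
    thr = threshold_otsu(exg)
    mask = exg > thr
    if min_size > 1:
        # drop components with fewer than min_size pixels
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return mask


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels; the four counts partition the image."""
    pred = _as_mask(pred)
    truth = _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def evaluate_mask(counts: ConfusionCounts, paper_literal: bool = False) -> dict:
    """IOU / PA / Recall from confusion counts.

    Undefined metrics (empty denominator) are returned as NaN with a warning.
    """
    if paper_literal:
        out = {
            "iou": _ratio(counts.tp, counts.tp + counts.fp + counts.tn),
            "pa": _ratio(counts.tp + counts.tn, counts.tp + counts.fp + counts.tn),
            "recall": _ratio(counts.tp, counts.tp + counts.tn),
        }
    else:
        out = {
            "iou": _ratio(counts.tp, counts.tp + counts.fp + counts.fn),
            "pa": _ratio(counts.tp + counts.tn, counts.total),
            "recall": _ratio(counts.tp, counts.tp + counts.fn),
        }
    for name, value in out.items():
        if np.isnan(value):
            warnings.warn(f"{name} undefined for counts {counts}")
    return out


def evaluate_pair(pred, truth, paper_literal: bool = False) -> dict:
    """Convenience: confusion counts then metric suite for one mask pair."""
    return evaluate_mask(confusion_counts(pred, truth), paper_literal=paper_literal)


def apply_mask(image, mask) -> np.ndarray:
    """Region-of-interest masking: background pixels set to (0, 0, 0)."""
    image = np.asarray(image)
    mask = _as_mask(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: {image.shape[:2]} vs {mask.shape}")
    return np.where(mask[..., None], image, 0)


def to_gray(image) -> np.ndarray:
    """Intensity channel I = (R + G + B) / 3 of the HSI colour space.

    Returned as float64 (the exact rational mean); use ``gray_to_uint8`` to
    materialise an 8-bit image with round-half-up.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return image.astype(np.float64).sum(axis=2) / 3.0


def gray_to_uint8(gray) -> np.ndarray:
    """8-bit materialisation of an intensity image, round-half-up."""
    return np.clip(np.floor(np.asarray(gray, dtype=float) + 0.5), 0, 255).astype(np.uint8)
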