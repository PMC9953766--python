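"""Pixel-level segmentation evaluation.

Confusion counts (TP/FP/TN/FN) are accumulated over the whole test dataset
and the summary metrics — precision, recall, F1, specificity, IoU (Jaccard),
accuracy — are computed from the accumulated counts, so large images weigh
proportionally to their pixel count. Per-image IoU is also provided (with
the empty-vs-empty convention IoU = 1), plus a TP/FP/FN overlay renderer
(teal = true positive, blue = false positive, green = false negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionAccumulator",
    "accumulate",
    "seg_metrics",
    "per_image_iou",
    "render_overlay",
]

# overlay tints (RGB)
_TP_COLOR = np.array([0, 128, 128], dtype=float)   # teal
_FP_COLOR = np.array([0, 0, 255], dtype=float)     # blue
_FN_COLOR = np.array([0, 255, 0], dtype=float)     # green


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return m.astype(bool)


@dataclass
class ConfusionAccumulator:
    """Dataset-level pixel confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def update(self, predicted: np.ndarray,
               truth: np.ndarray) -> "ConfusionAccumulator":
        return accumulate(self, predicted, truth)


def accumulate(acc: ConfusionAccumulator, predicted: np.ndarray,
               truth: np.ndarray) -> ConfusionAccumulator:
    """Add one image's pixel confusion counts to the accumulator.

    TP: p=1 ∧ g=1; FP: p=1 ∧ g=0; TN: p=0 ∧ g=0; FN: p=0 ∧ g=1.
    """
    p = _as_binary(predicted, "predicted")
    g = _as_binary(truth, "truth")
    if p.shape != g.shape:
        raise ValueError("predicted and truth shapes must match")
    acc.tp += int((p & g).sum())
    acc.fp += int((p & ~g).sum())
    acc.tn += int((~p & ~g).sum())
    acc.fn += int((~p & g).sum())
    return acc


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def seg_metrics(acc: ConfusionAccumulator, threshold: float = 0.5) -> dict:
    """Summary metrics from accumulated counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 harmonic mean;
    specificity = TN/(TN+FP); IoU = TP/(TP+FN+FP);
    accuracy = (TP+TN)/total. Zero denominators give a 0.0 sentinel and the
    metric's name is listed under ``zero_denominator_flags``.
    """
    flags: list[str] = []
    precision = _ratio(acc.tp, acc.tp + acc.fp, flags, "precision")
    recall = _ratio(acc.tp, acc.tp + acc.fn, flags, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, flags, "f1")
    specificity = _ratio(acc.tn, acc.tn + acc.fp, flags, "specificity")
    iou = _ratio(acc.tp, acc.tp + acc.fn + acc.fp, flags, "iou")
    accuracy = _ratio(acc.tp + acc.tn, acc.total, flags, "accuracy")
    return {
        "threshold": threshold,
        "TP": acc.tp, "FP": acc.fp, "TN": acc.tn, "FN": acc.fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": specificity,
        "iou": iou,
        "accuracy": accuracy,
        "zero_denominator_flags": flags,
    }


def per_image_iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Single-image Jaccard index; two empty masks count as identical (1.0)."""
    p = _as_binary(predicted, "predicted")
    g = _as_binary(truth, "truth")
    if p.shape != g.shape:
        raise ValueError("predicted and truth shapes must match")
    union = (p | g).sum()
    if union == 0:
        return 1.0
    return float((p & g).sum() / union)


def render_overlay(image: np.ndarray, predicted: np.ndarray,
                   truth: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend confusion tints over the image.

    False positives blue, false negatives green, true positives teal; true
    negatives untouched, so identical empty masks return the input image.
    """
    p = _as_binary(predicted, "predicted")
    g = _as_binary(truth, "truth")
    img = np.asarray(image, dtype=float)
    out = img.copy()
    for mask, color in (((p & g), _TP_COLOR),
                        ((p & ~g), _FP_COLOR),
                        ((~p & g), _FN_COLOR)):
        out[mask] = (1.0 - alpha) * img[mask] + alpha * color
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
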