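"""Tiled full-image segmentation inference with dihedral test-time augmentation.

A segmenter sees fixed-size square patches (448 x 448 by default). Whole-image
prediction therefore runs in three steps:

1. plan a grid of overlapping patches (stride = patch − overlap, last patch
   clamped to abut the border; images smaller than the patch are reflect-padded
   and the output cropped back);
2. predict each patch under the 8 dihedral augmentations (hflip x rot90),
   de-augment each output with the exact inverse, and average;
3. stitch patch maps back with uniform coverage-count weighting: each pixel's
   value is the mean of the patch predictions covering it.

The dihedral group guarantees invert(apply(x)) == x bitwise, so a segmenter
that is itself equivariant under the group yields a TTA output identical to
its direct prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "Augmentation",
    "DIHEDRAL_AUGMENTATIONS",
    "PatchGrid",
    "Segmenter",
    "apply_augmentation",
    "invert_augmentation",
    "pad_to_min",
    "plan_patch_grid",
    "tta_predict_patch",
    "predict_full_image",
    "threshold_mask",
    "TiledTTAPredictor",
]

PATCH_SIZE = 448
OVERLAP = 50


@runtime_checkable
class Segmenter(Protocol):
    """Anything mapping a patch (S x S x 3) to a probability map (S x S)."""

    def predict(self, patch: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class Augmentation:
    """One dihedral-group element: horizontal flip then k CCW quarter turns."""

    hflip: bool
    rot90_k: int

    def __post_init__(self) -> None:
        if self.rot90_k not in (0, 1, 2, 3):
            raise ValueError("rot90_k must be in {0,1,2,3}")


DIHEDRAL_AUGMENTATIONS: tuple[Augmentation, ...] = tuple(
    Augmentation(hflip=f, rot90_k=k) for f, k in product((False, True), range(4))
)


def _check_square(a: np.ndarray, k: int) -> None:
    if k % 2 == 1 and a.shape[0] != a.shape[1]:
        raise ValueError("odd quarter-turns require a square array")


def apply_augmentation(a: np.ndarray, aug: Augmentation) -> np.ndarray:
    """Horizontal flip (if set), then rotate 90° CCW ``rot90_k`` times."""
    _check_square(a, aug.rot90_k)
    if aug.hflip:
        a = a[:, ::-1]
    return np.rot90(a, aug.rot90_k)


def invert_augmentation(a: np.ndarray, aug: Augmentation) -> np.ndarray:
    """Exact inverse: rotate back, then un-flip. invert(apply(x)) == x."""
    _check_square(a, aug.rot90_k)
    a = np.rot90(a, -aug.rot90_k)
    if aug.hflip:
        a = a[:, ::-1]
    return a


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    overlap: int
    row_starts: tuple[int, ...]
    col_starts: tuple[int, ...]
    padded_height: int
    padded_width: int

    @property
    def starts(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.row_starts for c in self.col_starts]


def _axis_starts(dim: int, patch: int, stride: int) -> tuple[int, ...]:
    starts = [0]
    while starts[-1] + patch < dim:
        starts.append(min(starts[-1] + stride, dim - patch))
    return tuple(starts)


def plan_patch_grid(height: int, width: int, patch: int = PATCH_SIZE,
                    overlap: int = OVERLAP) -> PatchGrid:
    """Plan patch origins at stride patch − overlap, last start clamped.

    Axes shorter than the patch are planned on the reflect-padded size
    (``padded_height``/``padded_width``); every pixel ends up covered by at
    least one fully in-bounds patch.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    if overlap >= patch:
        raise ValueError("overlap must be smaller than the patch size")
    stride = patch - overlap
    ph, pw = max(height, patch), max(width, patch)
    return PatchGrid(
        patch_size=patch,
        overlap=overlap,
        row_starts=_axis_starts(ph, patch, stride),
        col_starts=_axis_starts(pw, patch, stride),
        padded_height=ph,
        padded_width=pw,
    )


def pad_to_min(a: np.ndarray, size: int) -> np.ndarray:
    """Reflect-pad the two leading axes up to at least ``size``."""
    pad_h = max(0, size - a.shape[0])
    pad_w = max(0, size - a.shape[1])
    if pad_h == 0 and pad_w == 0:
        return a
    width = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (a.ndim - 2)
    return np.pad(a, width, mode="reflect")


def _call_segmenter(segmenter, patch: np.ndarray,
                    origin: tuple[int, int] | None,
                    aug: Augmentation) -> np.ndarray:
    if getattr(segmenter, "requires_location", False):
        out = segmenter.predict(patch, origin=origin, augmentation=aug)
    else:
        out = segmenter.predict(patch)
    out = np.asarray(out, dtype=float)
    if out.shape != patch.shape[:2]:
        raise ValueError("segmenter output shape must match patch spatial shape")
    if out.min() < 0.0 or out.max() > 1.0:
        raise ValueError("segmenter output must lie in [0, 1]")
    return out


def tta_predict_patch(segmenter, patch: np.ndarray,
                      origin: tuple[int, int] | None = None) -> np.ndarray:
    """Average the de-augmented predictions over the 8 dihedral variants."""
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    acc = np.zeros(patch.shape[:2])
    for aug in DIHEDRAL_AUGMENTATIONS:
        out = _call_segmenter(segmenter, apply_augmentation(patch, aug),
                              origin, aug)
        acc += invert_augmentation(out, aug)
    return acc / len(DIHEDRAL_AUGMENTATIONS)


def predict_full_image(segmenter, image: np.ndarray, patch: int = PATCH_SIZE,
                       overlap: int = OVERLAP, tta: bool = True) -> np.ndarray:
    """Whole-image probability map via overlapping patches + TTA + stitching.

    Stitch weighting is uniform: a pixel covered by k patches gets the mean of
    the k patch values. Images smaller than the patch along an axis are
    reflect-padded for prediction and the map cropped back.
    """
    h, w = image.shape[:2]
    grid = plan_patch_grid(h, w, patch, overlap)
    padded = pad_to_min(image, patch)
    acc = np.zeros((grid.padded_height, grid.padded_width))
    cnt = np.zeros((grid.padded_height, grid.padded_width))
    for r, c in grid.starts:
        tile = padded[r:r + patch, c:c + patch]
        if tta:
            pm = tta_predict_patch(segmenter, tile, origin=(r, c))
        else:
            pm = _call_segmenter(segmenter, tile, (r, c),
                                 Augmentation(False, 0))
        acc[r:r + patch, c:c + patch] += pm
        cnt[r:r + patch, c:c + patch] += 1.0
    assert cnt.min() >= 1.0, "patch grid left pixels uncovered"
    return (acc / cnt)[:h, :w]


def threshold_mask(prob_map: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Binarize with a strict exceedance rule: pixel = 1 iff p > t."""
    p = np.asarray(prob_map)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return (p > t).astype(np.uint8)


class TiledTTAPredictor:
    """Convenience wrapper binding a segmenter to the tiled-TTA settings."""

    def __init__(self, segmenter, patch: int = PATCH_SIZE,
                 overlap: int = OVERLAP, tta: bool = True,
                 threshold: float = 0.5):
        self.segmenter = segmenter
        self.patch = patch
        self.overlap = overlap
        self.tta = tta
        self.threshold = threshold

    def predict_proba_map(self, image: np.ndarray) -> np.ndarray:
        return predict_full_image(self.segmenter, image, self.patch,
                                  self.overlap, self.tta)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        return threshold_mask(self.predict_proba_map(image), self.threshold)
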