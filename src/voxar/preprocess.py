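"""Rough heart-mask extraction, majority-vote mask fusion and the ROI.

The rating machinery needs only an approximate heart mask per image: Otsu
thresholding, largest-connected-component selection (26-connectivity) and
morphological closing plus hole filling.  Mapped per-condition masks are
fused by majority voting — a voxel is foreground when the fraction of masks
voting foreground reaches the threshold (0.5 at the rough affine stage, 0.8
for the refined per-condition masks) — and the analysis ROI is the voxelwise
intersection of the refined masks of every condition, so each database
contributes the same amount of information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

__all__ = ["RoiSet", "rough_mask", "fuse_masks", "build_roi"]

_CONN_26 = np.ones((3, 3, 3), dtype=bool)


def _mask_array(m) -> np.ndarray:
    arr = np.asarray(getattr(m, "data", m)) != 0
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
    return arr


def _image_array(v) -> np.ndarray:
    arr = np.asarray(getattr(v, "data", v), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {arr.shape}")
    return arr


@dataclass
class RoiSet:
    """Refined per-condition masks and their cross-condition intersection."""

    per_condition: dict[str, np.ndarray]
    roi: np.ndarray
    threshold: float


def rough_mask(
    v, min_component_voxels: int = 100, closing_radius: int = 3
) -> np.ndarray:
    """Approximate foreground mask of a bright structure on a dark background.

    Otsu threshold on the intensity histogram, keep the largest 26-connected
    component, then morphological closing with a ball structuring element and
    hole filling.  The result is deliberately rough; it only needs to enclose
    the structure of interest.
    """
    arr = _image_array(v)
    if float(arr.min()) == float(arr.max()):
        raise ValueError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(arr)
    fg = arr > thr
    if not fg.any():
        raise ValueError("Otsu threshold produced an empty foreground")
    labels, n = ndimage.label(fg, structure=_CONN_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_voxels:
        raise ValueError(
            f"largest component has {int(sizes[largest - 1])} voxels, "
            f"below the minimum of {min_component_voxels}"
        )
    mask = labels == largest
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=ball(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def fuse_masks(masks: Sequence, threshold: float) -> np.ndarray:
    """Majority-vote fusion: foreground iff votes/N >= threshold.

    The vote fraction is evaluated exactly (integer counts against
    ``threshold * N``), so a boundary case such as 16 votes out of 20 at
    threshold 0.8 is foreground.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    arrs = [_mask_array(m) for m in masks]
    if not arrs:
        raise ValueError("empty mask list")
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"mask geometry mismatch: {shape} vs {a.shape}")
    votes = np.zeros(shape, dtype=np.int32)
    for a in arrs:
        votes += a
    # >= with a small slack so that exact fractions like 16/20 vs 0.8 are
    # not lost to binary floating-point representation
    return votes >= threshold * len(arrs) - 1e-9


def build_roi(
    per_condition_masks: Mapping[str, Sequence], threshold: float = 0.8
) -> RoiSet:
    """Fuse each condition's mapped masks and intersect across conditions.

    All downstream similarity computation is restricted to the returned ROI.
    """
    if not per_condition_masks:
        raise ValueError("no condition masks provided")
    fused: dict[str, np.ndarray] = {}
    roi = None
    for cond in sorted(per_condition_masks):
        masks = per_condition_masks[cond]
        if len(masks) == 0:
            raise ValueError(f"condition {cond!r} has no mapped masks")
        fused[cond] = fuse_masks(masks, threshold)
        roi = fused[cond].copy() if roi is None else (roi & fused[cond])
    assert roi is not None
    if not roi.any():
        raise ValueError(
            "databases do not overlap on target: the intersection of the "
            "fused per-condition masks is empty"
        )
    return RoiSet(per_condition=fused, roi=roi, threshold=float(threshold))
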