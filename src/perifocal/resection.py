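"""Resection-cavity estimation and MRI-derived volumetrics.

The cavity is estimated purely from the pre- and post-surgical binary brain
volumes: both are morphologically closed (filling unassigned voxels left by
segmentation), the closed post volume is subtracted voxel-by-voxel from the
closed pre volume (tissue present before and absent after), and a
morphological opening strips the thin spurious rind that imperfect pre/post
co-registration leaves at the brain surface.

From the estimated cavity a derived post-surgical label volume is obtained
by zeroing labels inside it — segmenting a resected brain directly would
violate the segmenter's assumptions — and per-VOI resected volumes and
percentages follow by plain set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, LabelVolume, volume_mm3

__all__ = [
    "binarize_labels",
    "morph_close",
    "morph_open",
    "estimate_resection",
    "derive_post_labels",
    "resected_in_voi",
    "keep_largest_component",
    "ResectionResult",
]


def binarize_labels(labels: LabelVolume) -> BinaryMask:
    """Brain mask: every voxel with a nonzero label. Idempotent."""
    return BinaryMask(labels.grid, labels.data != 0)


def _ball(radius_voxels: int) -> np.ndarray:
    # Chebyshev ball: at radius 1 this is the 26-connected 3x3x3 element,
    # the smallest element that fills single-voxel gaps in any direction
    return np.ones((2 * radius_voxels + 1,) * 3, dtype=bool)


def morph_close(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Morphological closing (dilate then erode) with a ball element.

    Extensive: the output always contains the input. Radius 0 is the
    identity.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if radius_voxels == 0 or not mask.data.any():
        return BinaryMask(mask.grid, mask.data.copy())
    elem = _ball(radius_voxels)
    dil = ndimage.binary_dilation(mask.data, structure=elem)
    # erode treating outside the array as foreground, so closing stays
    # extensive even for objects touching the border
    closed = ndimage.binary_erosion(dil, structure=elem, border_value=1)
    return BinaryMask(mask.grid, closed | mask.data)


def morph_open(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Morphological opening (erode then dilate) with a ball element.

    Anti-extensive: the output is always contained in the input. Radius 0 is
    the identity.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if radius_voxels == 0 or not mask.data.any():
        return BinaryMask(mask.grid, mask.data.copy())
    opened = ndimage.binary_opening(mask.data, structure=_ball(radius_voxels))
    return BinaryMask(mask.grid, opened & mask.data)


def keep_largest_component(mask: BinaryMask) -> BinaryMask:
    """Optional cleanup: keep only the largest 26-connected component."""
    if not mask.data.any():
        return BinaryMask(mask.grid, mask.data.copy())
    cc, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=np.arange(1, n + 1))
    return BinaryMask(mask.grid, cc == (1 + int(np.argmax(sizes))))


def estimate_resection(
    pre_bin: BinaryMask,
    post_bin: BinaryMask,
    close_radius: int = 1,
    open_radius: int = 1,
    largest_component_only: bool = False,
) -> BinaryMask:
    """Estimate the resection cavity: ``open(close(pre) \\ close(post))``.

    Every member voxel was brain before surgery and is not brain after, up
    to the closing of segmentation gaps; the opening removes thin
    co-registration rinds. ``largest_component_only`` additionally keeps the
    single largest connected component (off by default).
    """
    if not pre_bin.grid.same_geometry(post_bin.grid):
        raise ValueError("pre and post masks must share a grid")
    diff = morph_close(pre_bin, close_radius) - morph_close(post_bin, close_radius)
    res = morph_open(diff, open_radius)
    if largest_component_only:
        res = keep_largest_component(res)
    return res


def derive_post_labels(pre_labels: LabelVolume, resvol: BinaryMask) -> LabelVolume:
    """Derived post-surgical label volume: labels zeroed inside the cavity."""
    if not pre_labels.grid.same_geometry(resvol.grid):
        raise ValueError("label volume and resection mask must share a grid")
    out = pre_labels.data.copy()
    out[resvol.data] = 0
    return LabelVolume(pre_labels.grid, out, dict(pre_labels.label_map))


def resected_in_voi(
    resvol: BinaryMask, voi: BinaryMask, voi_pre_mm3: float
) -> tuple[float, float]:
    """MRI-derived resected volume within a VOI and the percentage of the
    pre-surgical VOI volume it represents."""
    if voi_pre_mm3 <= 0:
        raise ValueError("pre-surgical VOI volume must be > 0")
    mm3 = volume_mm3(resvol & voi)
    return mm3, 100.0 * mm3 / voi_pre_mm3


@dataclass
class ResectionResult:
    """Cavity estimate plus the volumetrics derived from it."""

    resvol: BinaryMask
    derived_post_labels: LabelVolume
    resected_mm3: dict[str, float]
    resected_pct_of_voi: dict[str, float]
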