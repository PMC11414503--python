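"""HU-window segmentation of plaque components.

The workflow mirrors threshold-based plaque extraction in commercial CT
tooling: window the volume into calcified and non-calcified masks inside an
optional region of interest, union them into a whole-plaque mask, split the
union into connected components, and drop components below a minimum
physical volume (1 mm^3 by default).

Manual mask revision performed by radiologists in clinical workflows is
replaced by :func:`revise_mask`, a documented no-op hook: the automated
output is this package's contract.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import BinaryMask, HuWindow, ImageVolume, LabelMap

__all__ = [
    "threshold_mask",
    "union_masks",
    "label_components",
    "filter_by_volume",
    "revise_mask",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


def threshold_mask(
    vol: ImageVolume,
    window: HuWindow,
    roi: tuple[slice, slice, slice] | None = None,
) -> BinaryMask:
    """Voxels whose HU falls inside *window*, restricted to *roi*.

    *roi* is an axis-aligned voxel box given as three slices (0-based,
    half-open); voxels outside it are always False.
    """
    inside = window.contains(vol.intensities)
    if roi is not None:
        if len(roi) != 3:
            raise ValueError("roi must be three slices")
        box = np.zeros(vol.shape, dtype=bool)
        box[tuple(roi)] = True
        if not box.any():
            raise ValueError(f"empty ROI {roi} on grid {vol.shape}")
        inside &= box
    return BinaryMask(inside, vol.spacing, vol.origin)


def union_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Boolean union (voxelwise OR) of two masks on the same grid."""
    if not a.same_grid(b):
        raise ValueError(
            f"grid mismatch: {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}"
        )
    return BinaryMask(a.voxels | b.voxels, a.spacing, a.origin)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Maximal connected components, labelled 1..K in decreasing voxel count.

    Ties in size are broken by the component's first voxel in scan order, so
    the labelling is deterministic.
    """
    structure = connectivity_structure(connectivity)
    raw, n = ndimage.label(mask.voxels, structure=structure)
    if n == 0:
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), mask.spacing, mask.origin)
    counts = np.bincount(raw.ravel())[1:]
    # stable sort: equal-size components keep scipy's scan-order labelling
    order = np.argsort(-counts, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return LabelMap(remap[raw], mask.spacing, mask.origin)


def filter_by_volume(lm: LabelMap, min_volume: float = 1.0) -> LabelMap:
    """Drop components with physical volume < *min_volume* mm^3.

    Survivors are relabelled 1..K' preserving the size order. The 1 mm^3
    default reproduces the exclusion rule applied to both plaques and
    calcifications.
    """
    if min_volume < 0:
        raise ValueError("min_volume must be >= 0")
    volumes = lm.component_volumes()
    keep = np.flatnonzero(volumes >= min_volume) + 1
    remap = np.zeros(lm.n_components + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return LabelMap(remap[lm.labels], lm.spacing, lm.origin)


def revise_mask(mask: BinaryMask) -> BinaryMask:
    """Hook standing in for manual radiologist revision of a mask.

    Clinical workflows visually check thresholded masks on 2D planes and
    revise boundaries by hand (e.g. against calcification blooming). This
    package is fully automated, so the hook returns its input unchanged; it
    exists so a user can subclass or monkeypatch a revision step into the
    pipeline without changing the pipeline's structure.
    """
    return mask
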