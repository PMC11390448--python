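"""Organ-mask-guided cropping: bounding box, organ-bearing axial slices,
and per-slice 2D instances rescaled to a common shape."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import EmptyMaskError
from .geometry import Geometry


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis half-open voxel index ranges [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate bounding box: lo={self.lo}, hi={self.hi}")

    def contains_mask(self, mask: np.ndarray) -> bool:
        idx = np.argwhere(mask)
        if idx.size == 0:
            return True
        return bool(np.all(idx.min(axis=0) >= self.lo) and np.all(idx.max(axis=0) < self.hi))


@dataclass
class InstanceStack:
    """Ordered axial crops for one patient; all crops share one shape."""

    patient_id: str
    instances: np.ndarray  # (n, H, W)
    slice_indices: list[int]

    def __post_init__(self):
        if self.instances.ndim != 3:
            raise ValueError("instances must be a (n, H, W) array")
        if len(self.slice_indices) != self.instances.shape[0]:
            raise ValueError("slice_indices length mismatch")
        if any(b <= a for a, b in zip(self.slice_indices, self.slice_indices[1:])):
            raise ValueError("slice_indices must be strictly increasing")

    def __len__(self) -> int:
        return self.instances.shape[0]


def mask_bounding_box(mask: np.ndarray, margin_mm: float, geometry: Geometry) -> BoundingBox:
    """Tight box around positive voxels, dilated by margin_mm (ceil to voxels)
    per axis and clipped to the volume bounds."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise EmptyMaskError("mask has no positive voxel (segmentation error upstream)")
    margins = [math.ceil(margin_mm / s) for s in geometry.spacing]
    lo = [max(0, int(m) - g) for m, g in zip(idx.min(axis=0), margins)]
    hi = [min(n, int(m) + 1 + g) for m, g, n in zip(idx.max(axis=0), margins, mask.shape)]
    return BoundingBox(lo=tuple(lo), hi=tuple(hi))


def slices_with_organ(mask: np.ndarray) -> list[int]:
    """Axial indices whose 2D slice has at least one positive voxel, ascending."""
    has = np.asarray(mask).astype(bool).any(axis=(0, 1))
    return [int(i) for i in np.flatnonzero(has)]


def build_instances(
    image: np.ndarray,
    mask: np.ndarray,
    geometry: Geometry,
    margin_mm: float = 5.0,
    target_size: tuple[int, int] = (64, 64),
    patient_id: str = "P0",
) -> InstanceStack:
    """One 2D instance per organ-bearing axial slice.

    A single in-plane box (union over slices, plus margin) is shared by all
    instances so they align spatially; each crop is rescaled bilinearly to
    ``target_size``.
    """
    box = mask_bounding_box(mask, margin_mm, geometry)  # raises on empty mask
    organ_slices = slices_with_organ(mask)
    crops = []
    for k in organ_slices:
        crop = image[box.lo[0] : box.hi[0], box.lo[1] : box.hi[1], k]
        crops.append(
            resize(
                np.asarray(crop, dtype=np.float64),
                target_size,
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            )
        )
    return InstanceStack(
        patient_id=patient_id,
        instances=np.stack(crops, axis=0),
        slice_indices=organ_slices,
    )
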