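"""Series screening, resampling to homogeneous spacing, and global
intensity normalization.

Images are resampled with third-order spline interpolation; segmentation
masks with nearest-neighbor, so no new label values are introduced. The
output shape convention is ``round(shape * old_spacing / new_spacing)``
per axis, which keeps the identity case exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .geometry import Geometry

SPACING_TOLERANCE_MM = 1e-3

# exclusion checks run in this order; the first failing check wins
EXCLUSION_REASONS = (
    "incomplete_series",
    "inconsistent_spacing",
    "inconsistent_orientation",
    "segmentation_error",
)


@dataclass
class SeriesRecord:
    patient_id: str
    slice_indices: Sequence[int]
    pixel_spacings: Sequence[tuple[float, float]]
    orientations: Sequence[str]
    qa_flag: Optional[str] = None

    def __post_init__(self):
        if len(self.slice_indices) == 0:
            raise ConfigurationError(f"slice_indices: empty for patient {self.patient_id!r}")


@dataclass
class ExclusionReport:
    included: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [pid for pid, _ in self.excluded]

    def to_rows(self) -> list[dict]:
        rows = [{"patient_id": p, "status": "included", "reason": ""} for p in self.included]
        rows += [{"patient_id": p, "status": "excluded", "reason": r} for p, r in self.excluded]
        return rows


@dataclass(frozen=True)
class NormalizationStats:
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ConfigurationError(f"sd: must be > 0, got {self.sd}")


def failing_reasons(record: SeriesRecord) -> set[str]:
    """All defect categories a record falls into (unordered)."""
    reasons = set()
    idx = sorted(int(i) for i in record.slice_indices)
    if any(b - a != 1 for a, b in zip(idx, idx[1:])):
        reasons.add("incomplete_series")
    spacings = np.asarray(record.pixel_spacings, dtype=float)
    if spacings.size and np.any(np.abs(spacings - spacings[0]) > SPACING_TOLERANCE_MM):
        reasons.add("inconsistent_spacing")
    if len(set(record.orientations)) > 1:
        reasons.add("inconsistent_orientation")
    if record.qa_flag is not None:
        reasons.add("segmentation_error")
    return reasons


def screen_series(records: Sequence[SeriesRecord]) -> ExclusionReport:
    """Partition records into included / excluded-with-reason.

    A record failing several checks is excluded for the highest-priority
    reason in :data:`EXCLUSION_REASONS`; the reason is therefore independent
    of any evaluation order.
    """
    report = ExclusionReport()
    for record in records:
        reasons = failing_reasons(record)
        if reasons:
            winner = next(r for r in EXCLUSION_REASONS if r in reasons)
            report.excluded.append((record.patient_id, winner))
        else:
            report.included.append(record.patient_id)
    return report


def _target_shape(shape, old_spacing, new_spacing) -> tuple[int, ...]:
    return tuple(
        int(np.rint(n * o / t)) for n, o, t in zip(shape, old_spacing, new_spacing)
    )


def _resample(array: np.ndarray, geometry: Geometry, target_spacing, order: int):
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ConfigurationError(f"target_spacing: all entries must be > 0, got {target_spacing}")
    out_shape = _target_shape(array.shape, geometry.spacing, target_spacing)
    new_geometry = Geometry(spacing=target_spacing)
    if out_shape == array.shape and np.allclose(geometry.spacing, target_spacing):
        return array.copy(), new_geometry
    zoom = [o / i for o, i in zip(out_shape, array.shape)]
    out = ndimage.zoom(np.asarray(array, dtype=np.float64), zoom, order=order, mode="nearest")
    assert out.shape == out_shape
    return out, new_geometry


def resample_image(image: np.ndarray, geometry: Geometry, target_spacing) -> tuple[np.ndarray, Geometry]:
    """Cubic-spline resampling of intensity data to ``target_spacing``."""
    return _resample(image, geometry, target_spacing, order=3)


def resample_mask(mask: np.ndarray, geometry: Geometry, target_spacing) -> tuple[np.ndarray, Geometry]:
    """Nearest-neighbor resampling of a label/binary mask to ``target_spacing``."""
    out, geo = _resample(mask, geometry, target_spacing, order=0)
    return out.astype(mask.dtype), geo


def compute_normalization_stats(
    images: Sequence[np.ndarray], masks: Optional[Sequence[np.ndarray]] = None
) -> NormalizationStats:
    """Global mean/sd over a reference set, optionally restricted to mask
    foreground voxels (the training cohort's organ regions)."""
    if masks is None:
        values = np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in images])
    else:
        values = np.concatenate(
            [np.asarray(im, dtype=np.float64)[np.asarray(m).astype(bool)] for im, m in zip(images, masks)]
        )
    sd = float(values.std())
    if sd == 0.0:
        sd = 1.0  # degenerate constant reference set: shift only
    return NormalizationStats(mean=float(values.mean()), sd=sd)


def normalize_global(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(image - mean) / sd with frozen global statistics."""
    return (np.asarray(image, dtype=np.float64) - stats.mean) / stats.sd
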