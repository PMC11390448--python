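"""Seeded synthetic cohorts: anisotropic volumes with a small organ ellipsoid
and, for cases, a smaller high/low-contrast spherical lesion inside it.

Every downstream stage (cropping, bagging, pseudo-labeling, aggregation,
evaluation) is exercised against these phantoms, so generation is strictly
deterministic for a fixed (config, label, seed) triple.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

from .errors import ConfigurationError
from .geometry import AXIAL_AXIS, Geometry

# organ semi-axes as multiples of organ_radius along (x, y, z); the axial
# semi-axis is smallest so the organ occupies a minority of slices
_ORGAN_SEMIAXIS_SCALE = (1.0, 0.8, 0.6)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    organ_radius: float = 18.0  # mm
    tumor_radius: float = 6.0  # mm; 0 => control-only configuration
    organ_intensity: float = 100.0
    tumor_intensity: float = 200.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ConfigurationError(f"grid_shape: all axes must be >= 8, got {self.grid_shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing: all entries must be > 0, got {self.spacing}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.organ_radius <= 0:
            raise ConfigurationError(f"organ_radius: must be > 0, got {self.organ_radius}")
        if self.tumor_radius < 0:
            raise ConfigurationError(f"tumor_radius: must be >= 0, got {self.tumor_radius}")
        if self.tumor_radius > 0 and self.tumor_radius >= self.organ_radius:
            raise ConfigurationError(
                f"tumor_radius: must be < organ_radius, got {self.tumor_radius} >= {self.organ_radius}"
            )
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("n_cases/n_controls: must be >= 0")


@dataclass
class PhantomVolume:
    """One synthetic study: image, organ mask, tumor mask, geometry, label."""

    patient_id: str
    image: np.ndarray
    organ_mask: np.ndarray
    tumor_mask: np.ndarray
    geometry: Geometry
    label: int

    def check_invariants(self) -> None:
        assert self.tumor_mask.dtype == bool and self.organ_mask.dtype == bool
        if np.any(self.tumor_mask & ~self.organ_mask):
            raise AssertionError("tumor mask escapes organ mask")
        has_tumor = bool(self.tumor_mask.any())
        if has_tumor != (self.label == 1):
            raise AssertionError("label inconsistent with tumor mask")
        n_axial = self.organ_mask.shape[AXIAL_AXIS]
        n_organ = int(np.count_nonzero(self.organ_mask.any(axis=(0, 1))))
        if not 0 < n_organ < n_axial / 2:
            raise AssertionError(
                f"organ occupies {n_organ}/{n_axial} axial slices; expected a strict minority"
            )


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_coord(config: PhantomConfig):
    """Normalized ellipsoid radius u(p) per voxel; u <= 1 inside the organ."""
    shape = tuple(int(g) for g in config.grid_shape)
    xs, ys, zs = _voxel_centers_mm(shape, config.spacing)
    center = [(n - 1) * s / 2.0 for n, s in zip(shape, config.spacing)]
    semi = [config.organ_radius * k for k in _ORGAN_SEMIAXIS_SCALE]
    u = np.sqrt(
        ((xs - center[0]) / semi[0]) ** 2
        + ((ys - center[1]) / semi[1]) ** 2
        + ((zs - center[2]) / semi[2]) ** 2
    )
    return u, (xs, ys, zs), semi


def generate_patient(config: PhantomConfig, label: int, seed: int, patient_id: str = "P0") -> PhantomVolume:
    """Generate one phantom study. Deterministic for fixed (config, label, seed)."""
    config.validate()
    if label not in (0, 1):
        raise ConfigurationError(f"label: must be 0 or 1, got {label}")
    if label == 1 and config.tumor_radius <= 0:
        raise ConfigurationError("tumor_radius: must be > 0 to generate a case (label=1)")

    rng = np.random.default_rng(seed)
    u, (xs, ys, zs), semi = _ellipsoid_coord(config)
    organ = u <= 1.0

    tumor = np.zeros_like(organ)
    if label == 1:
        # candidate centers: deep enough inside the ellipsoid that the whole
        # sphere stays within the organ
        depth = 1.0 - config.tumor_radius / min(semi)
        candidates = np.flatnonzero(u.ravel() <= max(depth, 0.0))
        if candidates.size == 0:
            candidates = np.array([int(np.argmin(u))])
        pick = candidates[rng.integers(candidates.size)]
        cx, cy, cz = xs.ravel()[pick], ys.ravel()[pick], zs.ravel()[pick]
        dist = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2)
        tumor = (dist <= config.tumor_radius) & organ

    image = np.full(organ.shape, config.background_intensity, dtype=np.float64)
    image[organ] = config.organ_intensity
    image[tumor] = config.tumor_intensity
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)

    vol = PhantomVolume(
        patient_id=patient_id,
        image=image,
        organ_mask=organ,
        tumor_mask=tumor,
        geometry=Geometry(spacing=tuple(config.spacing)),
        label=int(label),
    )
    vol.check_invariants()
    return vol


def generate_cohort(config: PhantomConfig) -> list[PhantomVolume]:
    """Generate n_cases positive and n_controls negative studies.

    Per-patient seed = config.seed + patient index, so the cohort is
    reproducible without storing per-patient state.
    """
    config.validate()
    if config.n_cases + config.n_controls < 1:
        raise ConfigurationError("n_cases/n_controls: cohort must contain at least one patient")
    labels = [1] * config.n_cases + [0] * config.n_controls
    cohort = []
    for idx, label in enumerate(labels):
        cohort.append(
            generate_patient(config, label, seed=config.seed + idx, patient_id=f"P{idx:04d}")
        )
    return cohort


def _affine(geometry: Geometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = geometry.spacing
    return aff


def write_study(volume: PhantomVolume, directory: str) -> dict[str, str]:
    """Write image + masks as NIfTI with spacing in the header; returns paths."""
    try:
        os.makedirs(directory, exist_ok=True)
        aff = _affine(volume.geometry)
        paths = {}
        for name, arr, dtype in (
            ("image", volume.image, np.float32),
            ("organ_mask", volume.organ_mask, np.uint8),
            ("tumor_mask", volume.tumor_mask, np.uint8),
        ):
            path = os.path.join(directory, f"{volume.patient_id}_{name}.nii.gz")
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), path)
            paths[name] = path
        return paths
    except OSError as exc:
        raise OSError(f"failed writing study under {directory!r}: {exc}") from exc


def read_study(paths: dict[str, str], patient_id: str, label: int) -> PhantomVolume:
    """Round-trip reader for studies written by :func:`write_study`."""
    imgs = {name: nib.load(p) for name, p in paths.items()}
    spacing = tuple(float(z) for z in imgs["image"].header.get_zooms()[:3])
    return PhantomVolume(
        patient_id=patient_id,
        image=np.asarray(imgs["image"].dataobj, dtype=np.float64),
        organ_mask=np.asarray(imgs["organ_mask"].dataobj).astype(bool),
        tumor_mask=np.asarray(imgs["tumor_mask"].dataobj).astype(bool),
        geometry=Geometry(spacing=spacing),
        label=int(label),
    )


def with_overrides(config: PhantomConfig, **kwargs) -> PhantomConfig:
    return replace(config, **kwargs)
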