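"""Voxel-grid geometry carried alongside every volumetric array.

Arrays are indexed (x, y, z); the axial (slice) axis is the last one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

AXIAL_AXIS = 2


@dataclass(frozen=True)
class Geometry:
    """Physical spacing (mm per voxel, per axis) plus an axis-order tag."""

    spacing: tuple[float, float, float]
    axis_order: str = "xyz"

    def __post_init__(self):
        if len(self.spacing) != 3:
            raise ConfigurationError("spacing: expected 3 values")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing: all entries must be > 0, got {self.spacing}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def axial_axis(self) -> int:
        return AXIAL_AXIS
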