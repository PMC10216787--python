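"""Acquisition geometry of a high-content confocal z-stack.

A well is sampled as ``n_fields`` square fields of view; each field is a
z-stack of ``n_planes`` planes separated by ``z_step`` micrometres.  All
areas downstream (organoid sizes, the 250 um^2 debris filter, per-well
sampled area) derive from ``pixel_size`` via ``pixel_size ** 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["AcquisitionGeometry", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Field-of-view and z-sampling parameters.

    Parameters
    ----------
    field_area:
        Area of one square imaging field, in um^2.  The default matches a
        40x water-immersion objective on a 4-megapixel sCMOS camera
        (78,974.6 um^2 per field).
    n_planes:
        Number of z planes per field (default 15).
    z_step:
        Spacing between consecutive planes, in um (default 25).
    pixel_size:
        Lateral pixel size, in um/pixel (default 0.3).
    n_fields:
        Number of fields imaged per well (default 1).
    """

    field_area: float = 78_974.6
    n_planes: int = 15
    z_step: float = 25.0
    pixel_size: float = 0.3
    n_fields: int = 1

    def __post_init__(self) -> None:
        for name in ("field_area", "z_step", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if min(self.shape[1:]) < 1:
            raise ValueError("geometry yields a zero-pixel field")
        self.validate()

    @property
    def side_pixels(self) -> int:
        """Pixels along one side of the (square) field."""
        return max(1, round(math.sqrt(self.field_area) / self.pixel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_planes, rows, cols) of one field's single-channel stack."""
        n = self.side_pixels
        return (self.n_planes, n, n)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in um^2."""
        return self.pixel_size**2

    @property
    def realized_field_area(self) -> float:
        """Area actually covered by the pixel grid, in um^2.

        Differs from ``field_area`` by at most the rounding of the field
        side to whole pixels (validated to be within 1%).
        """
        n = self.side_pixels
        return (n * self.pixel_size) ** 2

    @property
    def sampled_area(self) -> float:
        """Total sampled area per well: ``n_fields * field_area`` (um^2)."""
        return self.n_fields * self.field_area

    @property
    def depth(self) -> float:
        """Axial extent covered by the stack, in um."""
        return (self.n_planes - 1) * self.z_step

    def validate(self) -> None:
        """Check the pixel grid reproduces ``field_area`` within 1%."""
        if abs(self.realized_field_area - self.field_area) > 0.01 * self.field_area:
            raise ValueError(
                f"field_area {self.field_area} not representable on a square "
                f"grid of {self.pixel_size} um pixels within 1% "
                f"(grid covers {self.realized_field_area:.1f} um^2)"
            )

    def plane_of(self, z: float) -> int:
        """Index of the plane nearest to axial position ``z`` (um)."""
        k = round(z / self.z_step)
        return min(max(k, 0), self.n_planes - 1)


DEFAULT_GEOMETRY = AcquisitionGeometry()
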