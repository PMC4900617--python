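"""Field geometry for a center-pivot irrigated plot.

A center pivot waters (and hence cultivates) a circular disc; every
downstream raster and point operation is restricted to that disc.  All
geometry lives in a projected plane with coordinates in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class FieldSpec:
    """Circular region of interest of a center-pivot field.

    Parameters
    ----------
    center_x, center_y : float
        Pivot-point coordinates in projected meters.
    radius : float
        Radius of the cultivated disc in meters.  The default study field
        of 23.5 ha corresponds to a radius of ~273.5 m.
    pixel_size : float
        Edge length in meters of the analysis grid cells laid over the
        field (10 m by default; satellite scenes use 30 m).
    """

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 273.5
    pixel_size: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def total_area_ha(self) -> float:
        """Disc area in hectares (pi * r^2 / 10^4)."""
        return math.pi * self.radius**2 / 1e4

    def contains(self, x, y) -> bool:
        """Whether point(s) (x, y) lie inside the pivot circle."""
        return (x - self.center_x) ** 2 + (y - self.center_y) ** 2 <= self.radius**2
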