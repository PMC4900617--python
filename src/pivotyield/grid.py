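"""Georeferenced single-band raster grids and grid-level operations.

The raster container follows the usual north-up convention: the origin is
the upper-left corner of the upper-left cell, rows run southward, columns
eastward, and cell centers sit at ``origin + (index + 0.5) * pixel``.
Grids are serialized as ESRI ASCII grid (a plain-text format readable by
any GIS) rather than a binary format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .field import FieldSpec

logger = logging.getLogger(__name__)

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster on a regular square-cell grid.

    Attributes
    ----------
    values : (nrows, ncols) float ndarray
        Cell values; entries under the mask are undefined.
    mask : (nrows, ncols) bool ndarray
        True where the cell is valid (inside the region of interest).
    x0, y0 : float
        Projected coordinates in meters of the upper-left corner.
    pixel : float
        Cell edge length in meters.
    units : str
        Unit label of the values (e.g. ``"t/ha"``, ``"reflectance"``).
    """

    values: np.ndarray
    mask: np.ndarray
    x0: float
    y0: float
    pixel: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel <= 0:
            raise ValueError(f"pixel size must be > 0, got {self.pixel}")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates in meters."""
        nr, nc = self.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.pixel
        ys = self.y0 - (np.arange(nr) + 0.5) * self.pixel
        return np.meshgrid(xs, ys)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.pixel - other.pixel) <= tol
        )

    def masked_values(self) -> np.ndarray:
        """1-D array of valid cell values."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """New grid on the same geometry with different values."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if units is not None:
            out.units = units
        return out

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.mask.copy(), self.x0, self.y0, self.pixel, self.units
        )


def grid_for_field(spec: FieldSpec, pixel: float | None = None, margin: float = 0.0) -> RasterGrid:
    """Empty (all-NaN) grid of unit mask covering the pivot circle.

    The grid is square, centered on the pivot point, and extends one
    half-pixel beyond the circle on each side plus any extra ``margin``.
    """
    p = spec.pixel_size if pixel is None else pixel
    half = spec.radius + margin
    n = int(np.ceil(2 * half / p))
    x0 = spec.center_x - n * p / 2.0
    y0 = spec.center_y + n * p / 2.0
    values = np.full((n, n), np.nan)
    mask = np.ones((n, n), dtype=bool)
    return RasterGrid(values, mask, x0, y0, p)


def make_pivot_mask(spec: FieldSpec, geometry: RasterGrid | None = None) -> RasterGrid:
    """Boolean raster: cell is True iff its center lies inside the circle.

    If ``geometry`` is omitted a grid just covering the circle is created.
    Raises if the circle is not fully inside the grid extent.
    """
    grid = grid_for_field(spec) if geometry is None else geometry
    nr, nc = grid.shape
    x_min, x_max = grid.x0, grid.x0 + nc * grid.pixel
    y_min, y_max = grid.y0 - nr * grid.pixel, grid.y0
    if (
        spec.center_x - spec.radius < x_min - grid.pixel / 2
        or spec.center_x + spec.radius > x_max + grid.pixel / 2
        or spec.center_y - spec.radius < y_min - grid.pixel / 2
        or spec.center_y + spec.radius > y_max + grid.pixel / 2
    ):
        raise ValueError("pivot circle extends outside the grid extent")
    X, Y = grid.cell_centers()
    inside = (X - spec.center_x) ** 2 + (Y - spec.center_y) ** 2 <= spec.radius**2
    if not inside.any():
        # degenerate: radius smaller than half a pixel -- keep the cell
        # whose center is nearest the pivot point
        d2 = (X - spec.center_x) ** 2 + (Y - spec.center_y) ** 2
        inside = d2 == d2.min()
    return RasterGrid(
        inside.astype(float), inside, grid.x0, grid.y0, grid.pixel, units="bool"
    )


def aggregate_to_grid(raster: RasterGrid, factor: int) -> RasterGrid:
    """Block-aggregate a raster by an integer factor (mean of unmasked cells).

    Each coarse cell is the mean of its unmasked fine cells; it is masked
    only when every constituent fine cell is masked.  Shapes that the
    factor does not divide are padded with masked cells (logged).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return raster.copy()
    nr, nc = raster.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    values = raster.values
    mask = raster.mask
    if pr or pc:
        logger.info("aggregate_to_grid: padding %dx%d grid by (%d, %d) masked cells", nr, nc, pr, pc)
        values = np.pad(values, ((0, pr), (0, pc)), constant_values=np.nan)
        mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=False)
    nrc, ncc = values.shape[0] // factor, values.shape[1] // factor
    v = np.where(mask, values, 0.0).reshape(nrc, factor, ncc, factor)
    m = mask.reshape(nrc, factor, ncc, factor)
    counts = m.sum(axis=(1, 3))
    sums = v.sum(axis=(1, 3))
    out_mask = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, sums / np.maximum(counts, 1), np.nan)
    return RasterGrid(
        out, out_mask, raster.x0, raster.y0, raster.pixel * factor, raster.units
    )


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """Write a raster as ESRI ASCII grid (text, nodata = -9999)."""
    nr, nc = raster.shape
    path = Path(path)
    vals = np.where(raster.mask, raster.values, _NODATA)
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {raster.x0!r}\n"
        f"yllcorner {raster.y0 - nr * raster.pixel!r}\n"
        f"cellsize {raster.pixel!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, units: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(t) for t in parts])
    nr, nc = int(header["nrows"]), int(header["ncols"])
    values = np.asarray(rows, dtype=float)
    if values.shape != (nr, nc):
        raise ValueError(f"grid body {values.shape} does not match header ({nr}, {nc})")
    nodata = header.get("nodata_value", _NODATA)
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    pixel = header["cellsize"]
    y0 = header["yllcorner"] + nr * pixel
    return RasterGrid(values, mask, header["xllcorner"], y0, pixel, units)
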