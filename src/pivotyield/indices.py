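"""Spectral vegetation indices and their per-cycle accumulation.

Seven standard indices plus the raw near-infrared band:

    SR    = NIR / R                                  (simple ratio)
    EVI   = 2.5 (NIR - R) / (NIR + 6 R - 7.5 B + 1)  (enhanced VI)
    NDVI  = (NIR - R) / (NIR + R)
    SAVI  = [(NIR - R) / (NIR + R + L)] (1 + L)      (soil-adjusted, L in [0, 1])
    GRVI  = (G - R) / (G + R)
    GNDVI = (NIR - G) / (NIR + G)
    LSWI  = (NIR - SWIR1) / (NIR + SWIR1)
    NIR   = the NIR band unchanged

The cumulative vegetation index (CVI) of a harvest cycle accumulates one
index across every image date in the cycle — by per-pixel sum (default) or
mean.  Useful identities (asserted in the test suite): SAVI with L = 0 is
exactly NDVI, and SR = (1 + NDVI) / (1 - NDVI) wherever R > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .scene import MultispectralScene

logger = logging.getLogger(__name__)

VI_KINDS = ("SR", "EVI", "NDVI", "SAVI", "GRVI", "GNDVI", "LSWI", "NIR")


@dataclass(frozen=True)
class VIKind:
    """An index selector; ``L`` is the SAVI soil-brightness factor."""

    name: str
    L: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in VI_KINDS:
            raise ValueError(f"unknown index {self.name!r}; choose from {VI_KINDS}")
        if not 0.0 <= self.L <= 1.0:
            raise ValueError(f"SAVI L must be in [0, 1], got {self.L}")


def _ratio(num: np.ndarray, den: np.ndarray, mask: np.ndarray):
    """num/den with zero-denominator cells masked out (counted, not raised)."""
    bad = mask & (den == 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("masking %d zero-denominator pixels", n_bad)
    out_mask = mask & ~bad
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(out_mask, num / np.where(den == 0, 1.0, den), np.nan)
    return out, out_mask


def compute_vi(scene: MultispectralScene, kind: VIKind | str) -> RasterGrid:
    """Compute one vegetation index raster from a scene.

    Negative reflectances (possible in atmospherically corrected data) are
    clipped to 0 with a logged count before the band math.  Cells where the
    index denominator is exactly zero are masked in the output.
    """
    if isinstance(kind, str):
        kind = VIKind(kind)
    mask = scene.mask
    bands = {}
    n_neg = 0
    for name, grid in scene.bands.items():
        v = grid.values
        neg = mask & (v < 0)
        n_neg += int(neg.sum())
        bands[name] = np.where(mask & (v < 0), 0.0, v)
    if n_neg:
        logger.info("clipped %d negative-reflectance pixels to 0", n_neg)
    B, G, R = bands["B"], bands["G"], bands["R"]
    NIR, SWIR1 = bands["NIR"], bands["SWIR1"]

    if kind.name == "NIR":
        out, out_mask = np.where(mask, NIR, np.nan), mask
    elif kind.name == "SR":
        out, out_mask = _ratio(NIR, R, mask)
    elif kind.name == "EVI":
        out, out_mask = _ratio(2.5 * (NIR - R), NIR + 6.0 * R - 7.5 * B + 1.0, mask)
    elif kind.name == "NDVI":
        out, out_mask = _ratio(NIR - R, NIR + R, mask)
    elif kind.name == "SAVI":
        out, out_mask = _ratio((NIR - R) * (1.0 + kind.L), NIR + R + kind.L, mask)
    elif kind.name == "GRVI":
        out, out_mask = _ratio(G - R, G + R, mask)
    elif kind.name == "GNDVI":
        out, out_mask = _ratio(NIR - G, NIR + G, mask)
    elif kind.name == "LSWI":
        out, out_mask = _ratio(NIR - SWIR1, NIR + SWIR1, mask)
    else:  # pragma: no cover - guarded by VIKind
        raise ValueError(kind.name)

    g = scene.grid
    label = kind.name if kind.name != "SAVI" else f"SAVI(L={kind.L})"
    return RasterGrid(out, out_mask, g.x0, g.y0, g.pixel, units=label)


def compute_cvi(rasters: list[RasterGrid], rule: str = "sum") -> RasterGrid:
    """Accumulate per-date index rasters of one harvest cycle per pixel.

    ``rule`` is ``"sum"`` (default) or ``"mean"``.  The output cell is
    masked wherever any input is masked, so the accumulation covers the
    same number of dates everywhere it is defined.
    """
    if not rasters:
        raise ValueError("empty raster list")
    if rule not in ("sum", "mean"):
        raise ValueError(f"rule must be 'sum' or 'mean', got {rule!r}")
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_geometry(r):
            raise ValueError("CVI inputs have mixed grid geometries")
    mask = np.logical_and.reduce([r.mask for r in rasters])
    stack = np.stack([np.where(r.mask, r.values, 0.0) for r in rasters])
    total = stack.sum(axis=0)
    if rule == "mean":
        total = total / len(rasters)
    out = np.where(mask, total, np.nan)
    label = f"C{ref.units}" if ref.units else "CVI"
    return RasterGrid(out, mask, ref.x0, ref.y0, ref.pixel, units=label)
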