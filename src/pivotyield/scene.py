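"""Multispectral scenes and harvest-cycle bookkeeping.

A scene is a dated stack of five surface-reflectance bands (blue, green,
red, near-infrared, shortwave-infrared-1) on a common grid — the band set
and 30 m cell size mirror a Landsat-8 style sensor.  A harvest cycle is
the regrowth period between consecutive cuts; each scene belongs to the
cycle whose cut it precedes, and its crop age is days since the previous
cut.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid

BAND_NAMES = ("B", "G", "R", "NIR", "SWIR1")


@dataclass
class MultispectralScene:
    """Five co-registered reflectance bands with acquisition metadata."""

    bands: dict[str, RasterGrid]
    date: _dt.date | None = None
    crop_age_days: int | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"scene is missing bands {missing}")
        ref = self.bands[BAND_NAMES[0]]
        for name in BAND_NAMES[1:]:
            if not ref.same_geometry(self.bands[name]):
                raise ValueError(f"band {name} geometry differs from band {BAND_NAMES[0]}")
            if not np.array_equal(ref.mask, self.bands[name].mask):
                raise ValueError(f"band {name} mask differs from band {BAND_NAMES[0]}")
        for name, band in self.bands.items():
            v = band.masked_values()
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError(f"band {name} reflectance outside [0, 1]")

    @property
    def grid(self) -> RasterGrid:
        return self.bands["NIR"]

    @property
    def mask(self) -> np.ndarray:
        return self.bands["NIR"].mask


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


@dataclass
class HarvestCycle:
    """One cut and the image acquisitions inside its regrowth window."""

    harvest_id: int
    cut_date: _dt.date
    previous_cut: _dt.date | None = None
    scene_dates: list[_dt.date] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cut_date = _as_date(self.cut_date)
        if self.previous_cut is not None:
            self.previous_cut = _as_date(self.previous_cut)
        self.scene_dates = [_as_date(d) for d in self.scene_dates]
        for d in self.scene_dates:
            if d > self.cut_date:
                raise ValueError(f"scene date {d} falls after cut {self.cut_date}")
            if self.previous_cut is not None and d <= self.previous_cut:
                raise ValueError(f"scene date {d} falls on/before previous cut {self.previous_cut}")

    def crop_age(self, scene_date) -> int | None:
        """Days since the previous cut; None if the previous cut is unknown."""
        if self.previous_cut is None:
            return None
        return (_as_date(scene_date) - self.previous_cut).days
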