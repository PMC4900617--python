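"""Yield-monitor point sets: loading, validation, cleaning, projection.

A baler-mounted hay yield monitor records, at each geo-referenced baling
location, the wet and dry hay yield (t/ha) and the moisture content of the
crop.  One :class:`YieldPointSet` holds the records of a single harvest
(cut); it is the regionalized variable that the variography and kriging
operate on.

All downstream geometry is in projected meters.  Files with lon/lat
coordinates must be loaded with ``coords="lonlat"`` so they pass through
the explicit local-projection step; mixing degrees into the metric math
fails loudly instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for on-disk CSV point files
COLUMNS = [
    "x",
    "y",
    "dry_yield_t_ha",
    "wet_yield_t_ha",
    "moisture_pct",
    "harvest_id",
    "timestamp",
]

_EARTH_RADIUS = 6_371_008.8  # mean Earth radius, meters


@dataclass
class YieldPointSet:
    """Georeferenced yield observations of one harvest.

    ``data`` is a DataFrame with (at least) columns ``x``, ``y`` in
    projected meters and ``dry_yield_t_ha``; optional columns follow
    :data:`COLUMNS`.  ``n_dropped`` counts input rows removed by the
    validity rules at load time.
    """

    data: pd.DataFrame
    harvest_id: int | None = None
    cut_date: str | None = None
    bloom_stage: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for col in ("x", "y", "dry_yield_t_ha"):
            if col not in self.data.columns:
                raise ValueError(f"point set is missing mandatory column {col!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected coordinates in meters."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def yields(self, which: str = "dry") -> np.ndarray:
        """Yield values in t/ha; ``which`` is ``"dry"`` (default) or ``"wet"``."""
        col = {"dry": "dry_yield_t_ha", "wet": "wet_yield_t_ha"}[which]
        if col not in self.data.columns:
            raise ValueError(f"point set has no column {col!r}")
        return self.data[col].to_numpy(dtype=float)


def lonlat_to_local_meters(
    lon: np.ndarray, lat: np.ndarray, lon0: float | None = None, lat0: float | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project lon/lat degrees to a local transverse-Mercator-style plane.

    The projection is centered on (``lon0``, ``lat0``) (defaulting to the
    data centroid); over a sub-kilometer field the flat-Earth small-angle
    form is accurate to well under a centimeter.
    Returns (x, y, (lon0, lat0)).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x = np.radians(lon - lon0) * _EARTH_RADIUS * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS
    return x, y, (lon0, lat0)


def _clean(df: pd.DataFrame, roi=None) -> tuple[pd.DataFrame, int]:
    """Apply the record validity rules; return (kept rows, dropped count).

    Rules: coordinates and dry yield finite; dry yield >= 0 (zeros kept);
    moisture in [0, 100); dry <= wet when both present; inside the ROI
    circle when one is given.
    """
    n0 = len(df)
    ok = np.isfinite(df["x"]) & np.isfinite(df["y"]) & np.isfinite(df["dry_yield_t_ha"])
    ok &= df["dry_yield_t_ha"] >= 0
    if "moisture_pct" in df.columns:
        m = df["moisture_pct"]
        ok &= m.isna() | ((m >= 0) & (m < 100))
    if "wet_yield_t_ha" in df.columns:
        w = df["wet_yield_t_ha"]
        ok &= w.isna() | (df["dry_yield_t_ha"] <= w + 1e-9)
    if roi is not None:
        ok &= roi.contains(df["x"].to_numpy(), df["y"].to_numpy())
    kept = df[ok].reset_index(drop=True)
    dropped = n0 - len(kept)
    if dropped:
        logger.info("dropped %d of %d yield records failing validity rules", dropped, n0)
    return kept, dropped


def read_yield_points(
    path: str | Path,
    format: str | None = None,
    column_map: dict[str, str] | None = None,
    coords: str = "projected",
    harvest_id: int | None = None,
    sheet: str | int = 0,
    roi=None,
) -> YieldPointSet:
    """Load and validate a yield-monitor point file (CSV or XLSX).

    ``column_map`` maps canonical names (see :data:`COLUMNS`) to the file's
    column headers; canonical headers are picked up automatically.
    ``coords="lonlat"`` projects degree coordinates to local meters.
    Invalid rows are dropped and counted, never silently altered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown format {format!r}")

    column_map = dict(column_map or {})
    rename = {src: canon for canon, src in column_map.items()}
    df = raw.rename(columns=rename)
    for col in ("x", "y", "dry_yield_t_ha"):
        if col not in df.columns:
            raise ValueError(
                f"mandatory column {col!r} not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
    df = df[[c for c in COLUMNS if c in df.columns]].copy()

    if coords == "lonlat":
        x, y, _ = lonlat_to_local_meters(df["x"].to_numpy(), df["y"].to_numpy())
        df["x"], df["y"] = x, y
    elif coords != "projected":
        raise ValueError("coords must be 'projected' or 'lonlat'")
    # guard against degree-like coordinates sneaking into metric math
    if coords == "projected":
        span = max(df["x"].max() - df["x"].min(), df["y"].max() - df["y"].min())
        if len(df) > 1 and span < 1.0 and df["x"].abs().max() < 360:
            raise ValueError(
                "coordinates look like degrees (span < 1); load with coords='lonlat'"
            )

    df, dropped = _clean(df, roi=roi)
    if len(df) == 0:
        raise ValueError(f"no valid yield records in {path.name}")
    if harvest_id is None and "harvest_id" in df.columns:
        ids = df["harvest_id"].dropna().unique()
        if len(ids) > 1:
            raise ValueError(f"file mixes harvest ids {sorted(ids)}; pass harvest_id")
        harvest_id = int(ids[0]) if len(ids) else None
    dup = df.duplicated(subset=[c for c in ("x", "y", "timestamp") if c in df.columns])
    if dup.any():
        logger.info("removing %d duplicate (x, y, timestamp) records", int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    return YieldPointSet(df, harvest_id=harvest_id, n_dropped=dropped)


def write_yield_points(points: YieldPointSet, path: str | Path) -> None:
    """Write a point set as RFC-4180 CSV with the canonical columns."""
    df = points.data.copy()
    if "harvest_id" not in df.columns and points.harvest_id is not None:
        df["harvest_id"] = points.harvest_id
    cols = [c for c in COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def dedupe_for_kriging(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at exactly coincident coordinates.

    Exact duplicates make the kriging system singular; variography keeps
    them (they inform the nugget) but the solver needs unique locations.
    """
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": values})
    g = df.groupby(["x", "y"], sort=False, as_index=False)["z"].mean()
    return g[["x", "y"]].to_numpy(), g["z"].to_numpy()
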