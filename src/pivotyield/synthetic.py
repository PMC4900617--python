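"""Synthetic center-pivot yield fields and co-registered reflectance scenes.

Everything downstream (variography, kriging, index math, reporting) is
exercised against fields generated here with *known* spatial structure:

* a stationary Gaussian random field with an exponential or spherical
  covariance (partial sill C, practical range a) plus independent nugget
  noise Co, masked to the pivot circle;
* a baler-track sampler that walks concentric circular passes — the
  harvesting pattern of a center-pivot field — and records a noisy yield
  reading every few meters, emulating a ~2000-point hay-yield-monitor file;
* a linear band emulator that couples each reflectance band to the latent
  yield surface (NIR rising with yield, red falling), giving scenes whose
  band-yield correlation is known in closed form:
  r = s * sigma_y / sqrt(s^2 sigma_y^2 + noise_sd^2) for slope s.

GRF synthesis is exact Cholesky on small grids (the reference path) and
circulant-embedding FFT on larger ones; both are driven by a single seed
and are bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .field import FieldSpec
from .grid import RasterGrid, grid_for_field, make_pivot_mask
from .points import YieldPointSet
from .scene import BAND_NAMES, MultispectralScene

logger = logging.getLogger(__name__)

#: largest cell count for which exact Cholesky synthesis is the default
_CHOLESKY_MAX_CELLS = 4096


@dataclass(frozen=True)
class GRFParams:
    """Gaussian-random-field parameters of a synthetic yield surface.

    ``nugget`` and ``partial_sill`` in (t/ha)^2, ``range_`` in meters
    (practical range), ``mean`` in t/ha.
    """

    form: str = "spherical"
    nugget: float = 0.5
    partial_sill: float = 1.0
    range_: float = 120.0
    mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "spherical"):
            raise ValueError(f"form must be exponential or spherical, got {self.form!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError(f"range must be > 0, got {self.range_}")


@dataclass(frozen=True)
class TrackSamplerParams:
    """Geometry and noise of the baler-track yield sampler.

    ``swath_spacing`` is the distance between concentric passes (the baler
    pickup width), ``along_track_spacing`` the distance between consecutive
    monitor records on a pass, both in meters.
    """

    swath_spacing: float = 12.0
    along_track_spacing: float = 10.0
    measurement_noise_sd: float = 0.0
    moisture_mean_pct: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swath_spacing <= 0 or self.along_track_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement noise sd must be >= 0")


@dataclass(frozen=True)
class BandCoupling:
    """Linear response of one band to yield: reflectance = a + b*yield + noise."""

    intercept: float
    slope: float
    noise_sd: float = 0.0


def _default_bands() -> dict[str, BandCoupling]:
    # NIR rises and red falls with canopy density; visible bands stay low.
    # NIR noise is set so that at a within-field yield sd of ~1.2 t/ha the
    # implied NIR-yield correlation is ~0.7, the observed per-scene maximum.
    return {
        "B": BandCoupling(0.06, -0.004, 0.005),
        "G": BandCoupling(0.10, -0.006, 0.006),
        "R": BandCoupling(0.12, -0.012, 0.010),
        "NIR": BandCoupling(0.15, 0.045, 0.055),
        "SWIR1": BandCoupling(0.30, -0.020, 0.020),
    }


@dataclass(frozen=True)
class BandCouplingModel:
    """Per-band linear coupling of reflectance to the latent yield surface."""

    bands: dict[str, BandCoupling] = field(default_factory=_default_bands)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"coupling model missing bands {missing}")

    @staticmethod
    def implied_r(slope: float, noise_sd: float, sigma_yield: float) -> float:
        """Closed-form band-yield Pearson correlation before clipping."""
        s = abs(slope) * sigma_yield
        return s / np.hypot(s, noise_sd) * np.sign(slope)

    @staticmethod
    def slope_for_r(r: float, noise_sd: float, sigma_yield: float) -> float:
        """Slope giving band-yield correlation ``r`` at the stated noise level."""
        if not -1 < r < 1:
            raise ValueError("r must be in (-1, 1)")
        if sigma_yield <= 0:
            raise ValueError("sigma_yield must be > 0")
        return r * noise_sd / (sigma_yield * np.sqrt(1 - r**2))


def _correlation(form: str, h: np.ndarray, a: float) -> np.ndarray:
    if form == "exponential":
        return np.exp(-3.0 * h / a)
    r = h / a
    return np.where(r < 1.0, 1.0 - 1.5 * r + 0.5 * r**3, 0.0)


def _grf_cholesky(coords: np.ndarray, form: str, sill: float, a: float, rng) -> np.ndarray:
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    cov = sill * _correlation(form, d, a)
    cov[np.diag_indices_from(cov)] += 1e-10 * max(sill, 1.0)
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(len(coords))


def _grf_fft(shape: tuple[int, int], pixel: float, form: str, sill: float, a: float, rng) -> np.ndarray:
    """Circulant-embedding synthesis of a stationary GRF on a full grid."""
    nr, nc = shape
    M = int(2 ** np.ceil(np.log2(2 * max(nr, nc))))
    j = np.minimum(np.arange(M), M - np.arange(M))
    hy, hx = np.meshgrid(j, j, indexing="ij")
    h = pixel * np.sqrt(hx.astype(float) ** 2 + hy.astype(float) ** 2)
    kernel = sill * _correlation(form, h, a)
    lam = np.fft.fft2(kernel).real
    neg = lam < 0
    if neg.any():
        frac = -lam[neg].sum() / lam[~neg].sum()
        if frac > 1e-3:
            logger.warning("circulant embedding clipped %.2g of spectral mass", frac)
        lam = np.clip(lam, 0.0, None)
    w = rng.standard_normal((M, M)) + 1j * rng.standard_normal((M, M))
    z = np.fft.fft2(np.sqrt(lam) * w) / M
    return z.real[:nr, :nc]


def simulate_yield_surface(
    spec: FieldSpec, params: GRFParams, method: str = "auto"
) -> RasterGrid:
    """Simulate a yield surface over the pivot circle.

    The surface is ``mean`` plus a zero-mean GRF with covariance
    C(h) = partial_sill * rho(h; form, range) plus independent nugget
    noise; cells outside the circle are masked.  ``method`` is ``"auto"``
    (Cholesky for <= 4096 cells, FFT beyond), ``"cholesky"`` or ``"fft"``.
    """
    geometry = grid_for_field(spec)
    mask_grid = make_pivot_mask(spec, geometry)
    mask = mask_grid.mask
    rng = np.random.default_rng(params.seed)
    nr, nc = geometry.shape
    values = np.full((nr, nc), float(params.mean))

    if params.partial_sill > 0:
        if method == "auto":
            method = "cholesky" if nr * nc <= _CHOLESKY_MAX_CELLS else "fft"
        if method == "cholesky":
            X, Y = geometry.cell_centers()
            coords = np.column_stack([X.ravel(), Y.ravel()])
            z = _grf_cholesky(
                coords, params.form, params.partial_sill, params.range_, rng
            ).reshape(nr, nc)
        elif method == "fft":
            z = _grf_fft(
                (nr, nc), geometry.pixel, params.form, params.partial_sill,
                params.range_, rng,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        values = values + z
    if params.nugget > 0:
        values = values + np.sqrt(params.nugget) * rng.standard_normal((nr, nc))

    values = np.where(mask, values, np.nan)
    return RasterGrid(values, mask, geometry.x0, geometry.y0, geometry.pixel, units="t/ha")


def _fill_nearest(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked cells by their nearest valid value (for interpolation)."""
    if mask.all():
        return values
    idx = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def _bilinear(surface: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    filled = _fill_nearest(surface.values, surface.mask)
    # fractional array indices of the sample points (row grows southward)
    col = (x - surface.x0) / surface.pixel - 0.5
    row = (surface.y0 - y) / surface.pixel - 0.5
    return ndimage.map_coordinates(filled, [row, col], order=1, mode="nearest")


def sample_yield_tracks(
    surface: RasterGrid,
    spec: FieldSpec,
    sampler: TrackSamplerParams,
    harvest_id: int = 1,
    cut_date: _dt.date | str | None = None,
) -> YieldPointSet:
    """Sample a yield surface along concentric baler passes.

    Passes are circles spaced ``swath_spacing`` apart starting half a swath
    from the pivot; records fall every ``along_track_spacing`` meters along
    each pass, with an independent random angular offset per pass.  Each
    record's dry yield is the bilinear surface value plus Gaussian
    measurement noise (negative readings are clipped to 0); wet yield is
    back-computed from a moisture draw around ``moisture_mean_pct``.
    """
    if not surface.mask.any():
        raise ValueError("surface has no unmasked cells")
    rng = np.random.default_rng(sampler.seed)
    radii = np.arange(sampler.swath_spacing / 2.0, spec.radius, sampler.swath_spacing)
    radii = radii[radii <= spec.radius - 1e-9]
    if len(radii) == 0:
        raise ValueError("field too small for the requested swath spacing")
    xs, ys = [], []
    for r in radii:
        m = max(1, int(np.floor(2 * np.pi * r / sampler.along_track_spacing)))
        theta = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(m) / m
        xs.append(spec.center_x + r * np.cos(theta))
        ys.append(spec.center_y + r * np.sin(theta))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    dry = _bilinear(surface, x, y)
    if sampler.measurement_noise_sd > 0:
        dry = dry + sampler.measurement_noise_sd * rng.standard_normal(len(x))
    dry = np.clip(dry, 0.0, None)
    moisture = np.clip(
        sampler.moisture_mean_pct + rng.standard_normal(len(x)), 0.5, 60.0
    )
    wet = dry / (1.0 - moisture / 100.0)
    base = (
        _dt.datetime.combine(_dt.date.fromisoformat(str(cut_date)), _dt.time(6, 0))
        if cut_date is not None
        else _dt.datetime(2000, 1, 1, 6, 0)
    )
    timestamps = [base + _dt.timedelta(seconds=2 * i) for i in range(len(x))]
    df = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "dry_yield_t_ha": dry,
            "wet_yield_t_ha": wet,
            "moisture_pct": moisture,
            "harvest_id": harvest_id,
            "timestamp": timestamps,
        }
    )
    logger.info("sampled %d yield points on %d passes", len(df), len(radii))
    return YieldPointSet(df, harvest_id=harvest_id,
                         cut_date=None if cut_date is None else str(cut_date))


def expected_track_count(spec: FieldSpec, sampler: TrackSamplerParams) -> int:
    """Geometric point-count oracle: sum over passes of circumference/spacing."""
    radii = np.arange(sampler.swath_spacing / 2.0, spec.radius, sampler.swath_spacing)
    return int(sum(max(1, int(np.floor(2 * np.pi * r / sampler.along_track_spacing)))
                   for r in radii))


def synthesize_scene(
    surface: RasterGrid,
    coupling: BandCouplingModel,
    date: _dt.date | str | None = None,
    crop_age_days: int | None = None,
    stage: str | None = None,
) -> MultispectralScene:
    """Emulate a multispectral acquisition over a yield surface.

    Each band is ``intercept + slope * yield + N(0, noise_sd^2)`` clipped to
    [0, 1]; a warning is logged when more than half the cells of a band need
    clipping (the linear emulator is then badly mis-specified).
    """
    rng = np.random.default_rng(coupling.seed)
    mask = surface.mask
    bands: dict[str, RasterGrid] = {}
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    for name in BAND_NAMES:
        c = coupling.bands[name]
        v = c.intercept + c.slope * surface.values
        if c.noise_sd > 0:
            v = v + c.noise_sd * rng.standard_normal(surface.shape)
        out_of_range = mask & ((v < 0) | (v > 1))
        if out_of_range.sum() > 0.5 * mask.sum():
            logger.warning(
                "band %s: %.0f%% of cells outside [0, 1] before clipping",
                name, 100 * out_of_range.sum() / mask.sum(),
            )
        v = np.clip(v, 0.0, 1.0)
        v = np.where(mask, v, np.nan)
        bands[name] = RasterGrid(
            v, mask.copy(), surface.x0, surface.y0, surface.pixel, units="reflectance"
        )
    return MultispectralScene(bands, date=date, crop_age_days=crop_age_days, stage=stage)
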