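"""Variography and ordinary (block) kriging for yield-monitor point data.

The spatial structure of yield Z is summarized by the empirical
semivariogram

    gamma(h) = 1 / (2 N(h)) * sum [Z(x_i) - Z(x_i + h)]^2

over the N(h) point pairs whose separation falls in the lag bin at h.  A
permissible model (exponential or spherical, Matheron forms) is fitted by
pair-count-weighted least squares; the form with the lower residual sum of
squares wins, with R^2 reported alongside.  The exponential model uses the
*practical range* convention rho(h) = exp(-3h/a) so that its fitted range
is comparable to the spherical range.

Kriging is ordinary (block) kriging: the value of each target block is the
weighted mean of nearby observations, with weights solving the
semivariance system under the unbiasedness constraint sum(lambda) = 1.
Block-to-point semivariances are averaged over a regular discretization of
the block; a 1-point discretization reduces exactly to point kriging.
Accuracy is assessed by leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .grid import RasterGrid
from .points import YieldPointSet, dedupe_for_kriging

logger = logging.getLogger(__name__)

FORMS = ("exponential", "spherical")

#: largest point count handled with a single dense pdist
_DENSE_MAX = 4000


# ---------------------------------------------------------------------------
# empirical semivariogram


@dataclass
class EmpiricalVariogram:
    """Binned semivariance vs lag distance.

    ``gamma`` is NaN for bins with no pairs (``counts == 0``).
    """

    lags: np.ndarray          # bin centers, meters
    gamma: np.ndarray         # semivariance per bin, (t/ha)^2
    counts: np.ndarray        # pair count per bin
    lag_width: float
    max_lag: float

    def nonempty(self) -> "EmpiricalVariogram":
        keep = self.counts > 0
        return EmpiricalVariogram(
            self.lags[keep], self.gamma[keep], self.counts[keep],
            self.lag_width, self.max_lag,
        )


def _pair_stats(coords: np.ndarray, values: np.ndarray, edges: np.ndarray):
    """Per-bin pair counts and summed squared differences.

    Uses a dense pdist for small n, otherwise chunks row blocks to bound
    memory at a few tens of MB.
    """
    n = len(coords)
    nb = len(edges) - 1
    counts = np.zeros(nb, dtype=np.int64)
    ssq = np.zeros(nb)
    max_lag = edges[-1]
    if n <= _DENSE_MAX:
        d = pdist(coords)
        dz2 = pdist(values[:, None], metric="sqeuclidean")
        sel = d <= max_lag
        idx = np.clip(np.searchsorted(edges, d[sel], side="right") - 1, 0, nb - 1)
        np.add.at(counts, idx, 1)
        np.add.at(ssq, idx, dz2[sel])
    else:
        block = 1000
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            # pairs within the block
            db = pdist(coords[i0:i1])
            zb = pdist(values[i0:i1, None], metric="sqeuclidean")
            sel = db <= max_lag
            idx = np.clip(np.searchsorted(edges, db[sel], side="right") - 1, 0, nb - 1)
            np.add.at(counts, idx, 1)
            np.add.at(ssq, idx, zb[sel])
            # pairs between the block and all later points
            if i1 < n:
                diff = coords[i0:i1, None, :] - coords[None, i1:, :]
                d = np.sqrt((diff**2).sum(axis=2)).ravel()
                dz2 = ((values[i0:i1, None] - values[None, i1:]) ** 2).ravel()
                sel = d <= max_lag
                idx = np.clip(np.searchsorted(edges, d[sel], side="right") - 1, 0, nb - 1)
                np.add.at(counts, idx, 1)
                np.add.at(ssq, idx, dz2[sel])
    return counts, ssq


def default_lag_width(coords: np.ndarray) -> float:
    """Twice the median nearest-neighbor distance (common variography rule)."""
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return 2.0 * float(np.median(d[:, 1]))


def empirical_variogram(
    points: YieldPointSet | tuple[np.ndarray, np.ndarray],
    lag_width: float | None = None,
    max_lag: float | None = None,
    which: str = "dry",
) -> EmpiricalVariogram:
    """Compute the binned empirical semivariogram of a point set.

    ``points`` is a :class:`YieldPointSet` or a plain ``(coords, values)``
    pair.  Defaults: lag width = 2x median nearest-neighbor distance;
    max lag = half the larger coordinate span.
    """
    if isinstance(points, YieldPointSet):
        coords, values = points.coords, points.yields(which)
    else:
        coords, values = points
        coords = np.asarray(coords, dtype=float)
        values = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points for a variogram")
    if lag_width is None:
        lag_width = default_lag_width(coords)
    if lag_width <= 0:
        raise ValueError(f"lag_width must be > 0, got {lag_width}")
    if max_lag is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        max_lag = float(max(span)) / 2.0
    nb = max(1, int(np.ceil(max_lag / lag_width)))
    edges = np.arange(nb + 1) * lag_width
    counts, ssq = _pair_stats(coords, values, edges)
    if counts.sum() == 0:
        raise ValueError("no point pairs within max_lag; variogram is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, ssq / np.maximum(2 * counts, 1), np.nan)
    lags = (edges[:-1] + edges[1:]) / 2.0
    return EmpiricalVariogram(lags, gamma, counts, float(lag_width), float(edges[-1]))


# ---------------------------------------------------------------------------
# permissible models


@dataclass
class VariogramModel:
    """A fitted permissible semivariogram model.

    ``nugget`` (Co) is the micro-scale + measurement variance, ``partial_sill``
    (C) the spatially structured variance, ``range_`` (a) the distance in
    meters at which the model (practically) reaches its sill Co + C.
    """

    form: str
    nugget: float
    partial_sill: float
    range_: float
    rss: float = np.nan
    r2: float = np.nan

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError(f"range must be > 0, got {self.range_}")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def proportion(self) -> float:
        return structural_proportion(self)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "sill": self.sill,
            "range_m": self.range_,
            "rss": self.rss,
            "r2": self.r2,
            "proportion": self.proportion,
        }


def model_semivariance(model: VariogramModel, h) -> np.ndarray:
    """Evaluate the model semivariance gamma(h); gamma(0) = 0 exactly.

    spherical:   Co + C (1.5 h/a - 0.5 (h/a)^3) for h <= a, else Co + C
    exponential: Co + C (1 - exp(-3 h/a))   [practical-range convention]
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("negative lag distance")
    return np.where(h == 0.0, 0.0, _gamma_cont(model, h))


def _gamma_cont(model: VariogramModel, h) -> np.ndarray:
    """Right-continuous semivariance: tends to the nugget Co as h -> 0+.

    Used for kriging right-hand sides, so that prediction at a datum's
    location smooths (is inexact) whenever the nugget is positive.
    """
    h = np.asarray(h, dtype=float)
    co, c, a = model.nugget, model.partial_sill, model.range_
    r = h / a
    if model.form == "spherical":
        return co + c * np.where(r < 1.0, 1.5 * r - 0.5 * r**3, 1.0)
    return co + c * (1.0 - np.exp(-3.0 * r))


def structural_proportion(model: VariogramModel) -> float:
    """Fraction C / (Co + C) of total variance that is spatially structured."""
    total = model.nugget + model.partial_sill
    if total <= 0:
        raise ValueError("total sill is zero; proportion undefined")
    return model.partial_sill / total


class VariogramFitError(RuntimeError):
    """All candidate model fits failed; carries per-form diagnostics."""

    def __init__(self, diagnostics: dict):
        super().__init__(f"variogram fit failed for all forms: {diagnostics}")
        self.diagnostics = diagnostics


def _fit_one_form(form, lags, gamma, weights, x0s):
    def resid(p):
        m = VariogramModel(form, max(p[0], 0.0), max(p[1], 0.0), max(p[2], 1e-9))
        return np.sqrt(weights) * (model_semivariance(m, lags) - gamma)

    best = None
    for x0 in x0s:
        try:
            sol = least_squares(
                resid, x0, bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]),
                method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return None
    rss, (co, c, a) = best
    model = VariogramModel(form, float(co), float(c), float(a), rss=rss)
    fitted = model_semivariance(model, lags)
    tss = float(np.sum((gamma - gamma.mean()) ** 2))
    model.r2 = 1.0 - float(np.sum((fitted - gamma) ** 2)) / tss if tss > 0 else 1.0
    return model


def fit_variogram(
    emp: EmpiricalVariogram,
    forms: tuple[str, ...] = FORMS,
    n_starts: int = 3,
    seed: int = 0,
) -> VariogramModel:
    """Fit candidate model forms and return the one with the lowest RSS.

    Weighted least squares with weights N(h); parameters constrained to
    Co, C >= 0 and a > 0.  Initialization: Co = min gamma, C = max - min,
    a = lag where gamma first reaches 95% of its maximum, with two extra
    jittered starts to escape local minima.  Ties between RSS and R^2
    rankings are broken by RSS.
    """
    e = emp.nonempty()
    if len(e.lags) < 4:
        raise ValueError(f"need >= 4 non-empty lag bins, got {len(e.lags)}")
    lags, gamma, w = e.lags, e.gamma, e.counts.astype(float)
    g_min, g_max = float(gamma.min()), float(gamma.max())
    co0 = max(g_min, 0.0)
    c0 = max(g_max - co0, 1e-6 + 0.1 * abs(g_max))
    reach = gamma >= 0.95 * g_max
    a0 = float(lags[np.argmax(reach)]) if reach.any() else float(lags[-1])
    a0 = max(a0, float(e.lag_width))
    rng = np.random.default_rng(seed)
    x0s = [np.array([co0, c0, a0])]
    for _ in range(max(0, n_starts - 1)):
        f = rng.uniform(0.5, 1.5, size=3)
        x0s.append(np.array([co0 * f[0] + 1e-6, c0 * f[1], a0 * f[2]]))

    fits = {}
    for form in forms:
        m = _fit_one_form(form, lags, gamma, w, x0s)
        if m is not None:
            fits[form] = m
    if not fits:
        raise VariogramFitError({f: "no convergence" for f in forms})
    return min(fits.values(), key=lambda m: m.rss)


# ---------------------------------------------------------------------------
# ordinary (block) kriging


@dataclass
class KrigingConfig:
    """Neighborhood and block settings for ordinary kriging.

    ``block_size`` is the square block edge in meters; ``block_disc`` the
    number of discretization points per side (1 => point kriging).
    ``search_radius`` of None means 1.5x the fitted range (>= ``min_radius``).
    """

    block_size: float = 10.0
    block_disc: int = 4
    max_neighbors: int = 16
    search_radius: float | None = None
    min_radius: float = 50.0

    def __post_init__(self) -> None:
        if self.block_size <= 0:
            raise ValueError("block size must be > 0")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if self.block_disc < 1:
            raise ValueError("block_disc must be >= 1")

    def radius_for(self, model: VariogramModel) -> float:
        if self.search_radius is not None:
            return self.search_radius
        return max(1.5 * model.range_, self.min_radius)


def _block_offsets(size: float, disc: int) -> np.ndarray:
    """(disc^2, 2) regular discretization offsets centered on the block."""
    if disc == 1:
        return np.zeros((1, 2))
    step = size / disc
    u = (np.arange(disc) + 0.5) * step - size / 2.0
    ox, oy = np.meshgrid(u, u)
    return np.column_stack([ox.ravel(), oy.ravel()])


def _gamma_within_block(model: VariogramModel, offsets: np.ndarray) -> float:
    """Mean model semivariance over all ordered pairs of block points."""
    if len(offsets) == 1:
        return 0.0
    diff = offsets[:, None, :] - offsets[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return float(model_semivariance(model, d.ravel()).mean())


def krige_points(
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    model: VariogramModel,
    config: KrigingConfig | None = None,
    block: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of ``values`` at ``targets``.

    Returns (estimates, kriging variances); targets with no neighbor inside
    the search radius get NaN.  With ``block=True`` the estimate is for the
    square block of ``config.block_size`` centered at each target,
    discretized by ``config.block_disc`` points per side.
    """
    config = config or KrigingConfig()
    coords, values = dedupe_for_kriging(np.asarray(coords, float), np.asarray(values, float))
    n = len(coords)
    if n < 1:
        raise ValueError("no data points")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    radius = config.radius_for(model)
    k = min(config.max_neighbors, n)
    offsets = _block_offsets(config.block_size, config.block_disc) if block else np.zeros((1, 2))
    g_bb = _gamma_within_block(model, offsets) if block else 0.0

    tree = cKDTree(coords)
    dists, idxs = tree.query(targets, k=k)
    if k == 1:
        dists, idxs = dists[:, None], idxs[:, None]

    est = np.full(len(targets), np.nan)
    var = np.full(len(targets), np.nan)
    for t in range(len(targets)):
        sel = dists[t] <= radius
        if not sel.any():
            continue
        nb = idxs[t][sel]
        pts = coords[nb]
        m = len(nb)
        # LHS: semivariances among neighbors + unbiasedness row/col
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=2))
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = _gamma_cont(model, dmat)
        np.fill_diagonal(A[:m, :m], 0.0)
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        # RHS: mean point-to-block semivariance over the discretization;
        # right-continuous at 0 so a positive nugget smooths at data sites
        disc_pts = targets[t][None, :] + offsets
        dd = np.sqrt(((pts[:, None, :] - disc_pts[None, :, :]) ** 2).sum(axis=2))
        g_pb = _gamma_cont(model, dd).mean(axis=1)
        b = np.empty(m + 1)
        b[:m] = g_pb
        b[m] = 1.0
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        lam, mu = sol[:m], sol[m]
        est[t] = float(lam @ values[nb])
        v = float(lam @ g_pb + mu - g_bb)
        if v < -1e-6:
            logger.warning("kriging variance %.3g < 0 at target %d; clipped", v, t)
        var[t] = max(v, 0.0)
    return est, var


def ordinary_kriging(
    points: YieldPointSet,
    model: VariogramModel,
    geometry: RasterGrid,
    config: KrigingConfig | None = None,
    which: str = "dry",
) -> tuple[RasterGrid, RasterGrid]:
    """Block-krige a yield point set onto a raster geometry.

    Every unmasked cell of ``geometry`` becomes one target block centered
    on the cell center.  Returns (estimate grid, kriging-variance grid);
    cells without neighbors in the search radius are masked.
    """
    config = config or KrigingConfig()
    if len(points) < 2:
        raise ValueError("need at least 2 points to krige")
    X, Y = geometry.cell_centers()
    tmask = geometry.mask
    targets = np.column_stack([X[tmask], Y[tmask]])
    est, var = krige_points(
        points.coords, points.yields(which), targets, model, config, block=True
    )
    out = np.full(geometry.shape, np.nan)
    out_var = np.full(geometry.shape, np.nan)
    out[tmask] = est
    out_var[tmask] = var
    ok = np.zeros(geometry.shape, dtype=bool)
    ok[tmask] = np.isfinite(est)
    return (
        RasterGrid(out, ok, geometry.x0, geometry.y0, geometry.pixel, units="t/ha"),
        RasterGrid(out_var, ok, geometry.x0, geometry.y0, geometry.pixel, units="(t/ha)^2"),
    )


@dataclass
class CrossValidationReport:
    """Leave-one-out kriging diagnostics."""

    predicted: np.ndarray
    observed: np.ndarray
    mean_error: float
    rmse: float
    r: float

    @property
    def n(self) -> int:
        return len(self.observed)

    def to_dict(self) -> dict:
        return {"n": self.n, "mean_error": self.mean_error, "rmse": self.rmse, "r": self.r}


def cross_validate(
    points: YieldPointSet,
    model: VariogramModel,
    config: KrigingConfig | None = None,
    which: str = "dry",
) -> CrossValidationReport:
    """Leave-one-out point kriging: each point predicted from all others."""
    config = config or KrigingConfig()
    coords, values = points.coords, points.yields(which)
    coords, values = dedupe_for_kriging(coords, values)
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 points for cross-validation")
    radius = config.radius_for(model)
    k = min(config.max_neighbors + 1, n)
    tree = cKDTree(coords)
    dists, idxs = tree.query(coords, k=k)
    pcfg = KrigingConfig(
        block_size=config.block_size, block_disc=1,
        max_neighbors=config.max_neighbors, search_radius=radius,
    )
    pred = np.full(n, np.nan)
    for i in range(n):
        keep = (idxs[i] != i) & (dists[i] <= radius)
        nb = idxs[i][keep][: config.max_neighbors]
        if len(nb) == 0:
            continue
        e, _ = krige_points(
            coords[nb], values[nb], coords[i][None, :], model, pcfg, block=False
        )
        pred[i] = e[0]
    ok = np.isfinite(pred)
    err = pred[ok] - values[ok]
    if ok.sum() >= 3 and np.std(pred[ok]) > 0 and np.std(values[ok]) > 0:
        r = float(pearsonr(pred[ok], values[ok])[0])
    else:
        r = np.nan
    return CrossValidationReport(
        predicted=pred[ok],
        observed=values[ok],
        mean_error=float(err.mean()) if len(err) else np.nan,
        rmse=float(np.sqrt((err**2).mean())) if len(err) else 0.0,
        r=r,
    )
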