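"""Descriptive statistics, yield-class areas, raster correlation and regression.

This is the reporting layer of the analysis: per-harvest descriptive
statistics of the monitor points (with adjusted skewness/kurtosis and
their standard errors), yield-class area tables cut at fixed breaks,
pairwise Pearson correlation matrices of co-registered rasters with
t-distribution p-values, and single-predictor regressions of yield on a
vegetation index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .grid import RasterGrid
from .points import YieldPointSet


@dataclass
class DescriptiveStats:
    """Moment summary of one harvest's yield values (t/ha).

    Skewness is the adjusted Fisher-Pearson g1 and kurtosis is adjusted
    excess kurtosis; their standard errors use the classical normal-theory
    approximations
        SE_skew = sqrt(6 n (n-1) / ((n-2)(n+1)(n+3)))
        SE_kurt = 2 SE_skew sqrt((n^2-1) / ((n-3)(n+5))).
    SEs are None for n < 4.
    """

    count: int
    min: float
    max: float
    mean: float
    std: float
    variance: float
    skewness: float | None = None
    skewness_se: float | None = None
    kurtosis: float | None = None
    kurtosis_se: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "count", "min", "max", "mean", "std", "variance",
            "skewness", "skewness_se", "kurtosis", "kurtosis_se",
        )}


def skewness_se(n: int) -> float:
    """Normal-theory standard error of sample skewness."""
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def kurtosis_se(n: int) -> float:
    """Normal-theory standard error of sample excess kurtosis."""
    return 2.0 * skewness_se(n) * math.sqrt((n**2 - 1) / ((n - 3.0) * (n + 5.0)))


def describe(points: YieldPointSet | np.ndarray, which: str = "dry") -> DescriptiveStats:
    """Descriptive statistics of one harvest's yield observations."""
    if isinstance(points, YieldPointSet):
        z = points.yields(which)
    else:
        z = np.asarray(points, dtype=float)
    z = z[np.isfinite(z)]
    n = len(z)
    if n == 0:
        raise ValueError("no finite values to describe")
    out = DescriptiveStats(
        count=n,
        min=float(z.min()),
        max=float(z.max()),
        mean=float(z.mean()),
        std=float(z.std(ddof=1)) if n > 1 else 0.0,
        variance=float(z.var(ddof=1)) if n > 1 else 0.0,
    )
    if n >= 3:
        out.skewness = float(sps.skew(z, bias=False))
    if n >= 4:
        out.kurtosis = float(sps.kurtosis(z, bias=False, fisher=True))
        out.skewness_se = skewness_se(n)
        out.kurtosis_se = kurtosis_se(n)
    return out


# ---------------------------------------------------------------------------
# yield-class areas

DEFAULT_CLASS_EDGES = (2.0, 3.0, 4.0, 5.0)


@dataclass
class YieldClassTable:
    """Area (ha) and share (%) of the field in each yield band.

    Intervals are closed on the left, open on the right, with open-ended
    extremes: ``< e0``, ``[e0, e1)``, ..., ``>= e_last``.
    """

    labels: list[str]
    areas_ha: list[float]
    shares_pct: list[float]
    average_yield: float
    total_area_ha: float

    def to_dict(self) -> dict:
        return {
            "classes": [
                {"range_t_ha": l, "area_ha": a, "share_pct": s}
                for l, a, s in zip(self.labels, self.areas_ha, self.shares_pct)
            ],
            "average_yield_t_ha": self.average_yield,
            "total_area_ha": self.total_area_ha,
        }


def classify_yield(
    raster: RasterGrid, edges: tuple[float, ...] = DEFAULT_CLASS_EDGES
) -> YieldClassTable:
    """Tabulate the area of each yield class on a (kriged) yield map."""
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    z = raster.masked_values()
    if z.size == 0:
        raise ValueError("empty raster")
    cell_ha = raster.pixel**2 / 1e4
    bins = np.concatenate([[-np.inf], edges, [np.inf]])
    counts, _ = np.histogram(z, bins=bins)
    areas = counts * cell_ha
    total = z.size * cell_ha
    shares = 100.0 * counts / z.size
    labels = (
        [f"< {edges[0]:g}"]
        + [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
        + [f"> {edges[-1]:g}"]
    )
    return YieldClassTable(
        labels=labels,
        areas_ha=[float(a) for a in areas],
        shares_pct=[float(s) for s in shares],
        average_yield=float(z.mean()),
        total_area_ha=float(total),
    )


# ---------------------------------------------------------------------------
# raster correlation and regression


def correlate_grids(a: RasterGrid, b: RasterGrid) -> tuple[float, float, int]:
    """Pearson correlation of two co-registered rasters over shared cells.

    Returns (r, two-tailed p, n).  p comes from t = r sqrt(n-2)/sqrt(1-r^2)
    on n-2 degrees of freedom.
    """
    if not a.same_geometry(b):
        raise ValueError("grids are not co-registered")
    shared = a.mask & b.mask
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"need >= 3 shared unmasked cells, got {n}")
    x = a.values[shared]
    y = b.values[shared]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the grids; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r**2)
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, p, n


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationReport:
    """Pairwise correlation matrix with p-values and significance stars."""

    names: list[str]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    stars: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "r": [[round(v, 10) for v in row] for row in self.r.tolist()],
            "p": self.p.tolist(),
            "n": self.n.tolist(),
            "stars": self.stars,
        }


def correlation_matrix(
    grids: dict[str, RasterGrid], include_total: bool = False
) -> CorrelationReport:
    """Pairwise Pearson correlations of named co-registered rasters.

    With ``include_total=True`` a "total" grid (per-cell sum of all inputs,
    defined on their shared mask) is appended — the seasonal total-yield
    map when the inputs are per-harvest yield maps.
    """
    if len(grids) < 2:
        raise ValueError("need at least 2 grids")
    grids = dict(grids)
    if include_total:
        names = list(grids)
        ref = grids[names[0]]
        shared = np.logical_and.reduce([g.mask for g in grids.values()])
        total = np.where(shared, sum(np.where(g.mask, g.values, 0.0) for g in grids.values()), np.nan)
        grids["total"] = RasterGrid(total, shared, ref.x0, ref.y0, ref.pixel, units=ref.units)
    names = list(grids)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(grids[names[i]].mask.sum())
        for j in range(i + 1, k):
            rij, pij, nij = correlate_grids(grids[names[i]], grids[names[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    stars = [[_stars(p[i, j]) if i != j else "" for j in range(k)] for i in range(k)]
    return CorrelationReport(names=names, r=r, p=p, n=n, stars=stars)


@dataclass
class RegressionResult:
    """Ordinary least squares of yield on a single predictor raster."""

    slope: float
    intercept: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r2": self.r2, "n": self.n}


def regress_yield_on_index(yield_grid: RasterGrid, vi: RasterGrid) -> RegressionResult:
    """Regress yield on one vegetation-index raster over shared cells."""
    if not yield_grid.same_geometry(vi):
        raise ValueError("grids are not co-registered")
    shared = yield_grid.mask & vi.mask
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"need >= 3 shared unmasked cells, got {n}")
    x = vi.values[shared]
    y = yield_grid.values[shared]
    if np.std(x) == 0:
        raise ValueError("zero predictor variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=n,
    )
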