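"""Config-driven orchestration of the full yield-variability analysis.

The pipeline reproduces, per harvest: point loading/cleaning, descriptive
statistics, variography and model fitting, ordinary block kriging at 10 m,
leave-one-out cross-validation, aggregation to the 30 m satellite grid and
yield classification; per harvest cycle: vegetation indices of every scene
and their cumulative index; and finally the cross-harvest correlation
matrix (with the seasonal total-yield map), CVI-yield correlations and
per-image yield~index regressions.

``simulate_study`` generates the whole input set synthetically — four
harvests sharing a latent field (so cross-harvest map correlations are
tunable through ``latent_share``) plus dated scenes — and feeds it through
``run_pipeline``.  A single global seed fans out to per-stage child seeds
by stable hashing of stage names, so adding a stage never perturbs the
random stream of another.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .field import FieldSpec
from .geostat import (
    KrigingConfig,
    cross_validate,
    empirical_variogram,
    fit_variogram,
    ordinary_kriging,
)
from .grid import RasterGrid, aggregate_to_grid, grid_for_field, make_pivot_mask, write_ascii_grid
from .indices import VIKind, compute_cvi, compute_vi
from .points import YieldPointSet, read_yield_points, write_yield_points
from .scene import MultispectralScene
from .stats import (
    classify_yield,
    correlate_grids,
    correlation_matrix,
    describe,
    regress_yield_on_index,
)
from .synthetic import (
    BandCoupling,
    BandCouplingModel,
    GRFParams,
    TrackSamplerParams,
    sample_yield_tracks,
    simulate_yield_surface,
    synthesize_scene,
    _default_bands,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def child_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# configuration

#: image dates, crop ages (days) and phenological stages of the four
#: default harvest cycles (October 2013 - May 2014 study calendar)
DEFAULT_HARVESTS: list[dict] = [
    {
        "id": 8, "cut_date": "2013-12-05", "previous_cut": "2013-10-20",
        "mean": 2.32, "form": "exponential", "nugget": 0.02, "partial_sill": 0.05,
        "scenes": [
            {"date": "2013-11-03", "age": 14, "stage": "Vegetative"},
            {"date": "2013-11-10", "age": 21, "stage": "Late bud stage"},
            {"date": "2013-11-26", "age": 37, "stage": "10% bloom"},
            {"date": "2013-12-05", "age": 46, "stage": "50% bloom"},
        ],
    },
    {
        "id": 9, "cut_date": "2014-02-16", "previous_cut": "2013-12-05",
        "mean": 2.45, "form": "spherical", "nugget": 0.54, "partial_sill": 0.93,
        "scenes": [
            {"date": "2013-12-21", "age": 16, "stage": "Vegetative"},
            {"date": "2013-12-28", "age": 23, "stage": "Vegetative"},
            {"date": "2014-01-13", "age": 39, "stage": "Dormant"},
            {"date": "2014-01-22", "age": 48, "stage": "Vegetative"},
            {"date": "2014-01-29", "age": 55, "stage": "Early bud stage"},
            {"date": "2014-02-14", "age": 71, "stage": "10% bloom"},
        ],
    },
    {
        "id": 10, "cut_date": "2014-04-02", "previous_cut": "2014-02-16",
        "mean": 2.86, "form": "spherical", "nugget": 0.67, "partial_sill": 2.21,
        "scenes": [
            {"date": "2014-03-02", "age": 14, "stage": "Vegetative"},
            {"date": "2014-03-11", "age": 23, "stage": "Early bud stage"},
            {"date": "2014-03-18", "age": 30, "stage": "Late bud stage"},
            {"date": "2014-03-27", "age": 39, "stage": "10% bloom"},
        ],
    },
    {
        "id": 11, "cut_date": "2014-05-06", "previous_cut": "2014-04-02",
        "mean": 4.01, "form": "spherical", "nugget": 1.43, "partial_sill": 2.82,
        "scenes": [
            {"date": "2014-04-12", "age": 10, "stage": "Vegetative"},
            {"date": "2014-04-19", "age": 17, "stage": "Early bud stage"},
            {"date": "2014-04-28", "age": 26, "stage": "Late bud stage"},
            {"date": "2014-05-05", "age": 34, "stage": "10% bloom"},
        ],
    },
]


def default_study_config(seed: int = 0) -> dict:
    """Configuration of the synthetic four-harvest center-pivot study.

    Field geometry, per-harvest means and nugget/sill structure, and the
    image calendar mirror the study conditions; the spatial range (120 m)
    and track sampler density are generator choices documented in the
    methods note.
    """
    return {
        "seed": seed,
        "field": {"center_x": 0.0, "center_y": 0.0, "radius": 273.5, "pixel_size": 10.0},
        "yield_column": "dry",
        "range_m": 120.0,
        "latent_share": 0.8,
        # measurement_noise_sd of None means sqrt(nugget) per harvest: the
        # monitor's reading error is what produces the nugget at point support
        "sampler": {
            "swath_spacing": 12.0,
            "along_track_spacing": 10.0,
            "measurement_noise_sd": None,
        },
        "coupling": {"nir_slope": 0.045, "nir_noise_sd": 0.055},
        "variogram": {"lag_width": None, "max_lag": None},
        "kriging": {
            "block_size": 10.0, "block_disc": 4, "max_neighbors": 16,
            "search_radius": None,
        },
        "aggregate_factor": 3,
        "classes": [2.0, 3.0, 4.0, 5.0],
        "vi": {"kinds": ["NIR", "SAVI", "NDVI", "EVI", "GNDVI", "GRVI", "LSWI", "SR"],
               "savi_L": 0.5, "cvi_rule": "sum"},
        "harvests": DEFAULT_HARVESTS,
    }


def load_config(path: str | Path) -> dict:
    """Load a pipeline config from a YAML file, filling defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_study_config(user.get("seed", 0))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _field_spec(cfg: dict) -> FieldSpec:
    f = cfg["field"]
    return FieldSpec(f["center_x"], f["center_y"], f["radius"], f["pixel_size"])


def _kriging_config(cfg: dict) -> KrigingConfig:
    k = cfg["kriging"]
    return KrigingConfig(
        block_size=k["block_size"], block_disc=k["block_disc"],
        max_neighbors=k["max_neighbors"], search_radius=k["search_radius"],
    )


# ---------------------------------------------------------------------------
# study data and synthesis


@dataclass
class StudyData:
    """In-memory inputs of one pipeline run."""

    points: dict[int, YieldPointSet]
    scenes: dict[int, list[MultispectralScene]] = field(default_factory=dict)
    surfaces: dict[int, RasterGrid] = field(default_factory=dict)  # latent truth, if known


def synthesize_study_data(cfg: dict) -> StudyData:
    """Generate the four-harvest synthetic study inputs.

    Each harvest surface is mean_h + sqrt(C_h) * (sqrt(s) L0 + sqrt(1-s) L_h)
    + nugget noise, where L0 is a latent unit-sill field shared by all
    harvests, L_h are independent, and s = ``latent_share``.  Yield points
    come from the baler-track sampler; each scene is the linear band
    emulator applied to the 30 m aggregated surface.
    """
    spec = _field_spec(cfg)
    seed = cfg["seed"]
    s = float(cfg["latent_share"])
    if not 0.0 <= s <= 1.0:
        raise ValueError("latent_share must be in [0, 1]")
    rng_range = float(cfg["range_m"])

    def unit_field(form: str, stage: str) -> RasterGrid:
        g = simulate_yield_surface(
            spec,
            GRFParams(form=form, nugget=0.0, partial_sill=1.0, range_=rng_range,
                      mean=0.0, seed=child_seed(seed, stage)),
        )
        # condition to zero ROI-average so each harvest's field mean equals
        # its specified mean (one realization of a GRF has a nonzero mean)
        g.values = g.values - g.masked_values().mean()
        return g

    latent = unit_field("spherical", "latent")
    coupling_cfg = cfg.get("coupling", {})
    bands = _default_bands()
    if "nir_slope" in coupling_cfg:
        bands["NIR"] = BandCoupling(
            bands["NIR"].intercept, coupling_cfg["nir_slope"],
            coupling_cfg.get("nir_noise_sd", bands["NIR"].noise_sd),
        )

    points: dict[int, YieldPointSet] = {}
    scenes: dict[int, list[MultispectralScene]] = {}
    surfaces: dict[int, RasterGrid] = {}
    smp = cfg["sampler"]
    for h in cfg["harvests"]:
        hid = int(h["id"])
        own = unit_field(h["form"], f"harvest{hid}/structure")
        structured = np.sqrt(h["partial_sill"]) * (
            np.sqrt(s) * latent.values + np.sqrt(1.0 - s) * own.values
        )
        vals = h["mean"] + structured
        vals = np.where(latent.mask, np.clip(vals, 0.0, None), np.nan)
        surface = RasterGrid(vals, latent.mask.copy(), latent.x0, latent.y0,
                             latent.pixel, units="t/ha")
        surfaces[hid] = surface
        # the monitor's reading error plays the nugget at point support
        noise_sd = smp["measurement_noise_sd"]
        if noise_sd is None:
            noise_sd = float(np.sqrt(h["nugget"]))
        sampler = TrackSamplerParams(
            swath_spacing=smp["swath_spacing"],
            along_track_spacing=smp["along_track_spacing"],
            measurement_noise_sd=noise_sd,
            seed=child_seed(seed, f"harvest{hid}/tracks"),
        )
        points[hid] = sample_yield_tracks(
            surface, spec, sampler, harvest_id=hid, cut_date=h["cut_date"]
        )
        surface30 = aggregate_to_grid(surface, cfg["aggregate_factor"])
        scenes[hid] = []
        for sc in h.get("scenes", []):
            coupling = BandCouplingModel(
                bands=bands, seed=child_seed(seed, f"harvest{hid}/scene{sc['date']}")
            )
            scenes[hid].append(
                synthesize_scene(
                    surface30, coupling, date=sc["date"],
                    crop_age_days=sc.get("age"), stage=sc.get("stage"),
                )
            )
    return StudyData(points=points, scenes=scenes, surfaces=surfaces)


def load_study_data(cfg: dict) -> StudyData:
    """Load study inputs from the file paths named in the config."""
    points: dict[int, YieldPointSet] = {}
    for h in cfg["harvests"]:
        hid = int(h["id"])
        if "points" not in h:
            raise ValueError(f"harvest {hid}: no 'points' path and not synthetic")
        points[hid] = read_yield_points(
            h["points"], column_map=h.get("column_map"),
            coords=h.get("coords", "projected"), harvest_id=hid,
        )
    return StudyData(points=points)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunManifest:
    """Per-stage record of one pipeline run."""

    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, t0: float, **info) -> None:
        self.stages.append({"stage": name, "wall_s": round(time.time() - t0, 3), **info})

    def to_dict(self) -> dict:
        return {"seed": self.seed, "version": self.version, "stages": self.stages}


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_text_table(rows: list[list], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = [[f"{v:.4f}" if isinstance(v, float) else str(v) for v in row] for row in rows]
    widths = [max(len(r[i]) for r in cells) for i in range(len(cells[0]))]
    with path.open("w") as fh:
        for row in cells:
            fh.write("  ".join(c.rjust(w) for c, w in zip(row, widths)) + "\n")


def run_pipeline(cfg: dict, data: StudyData, out_dir: str | Path) -> RunManifest:
    """Execute the full analysis on in-memory study data.

    Writes, under ``out_dir``: one directory per harvest (points CSV, 10 m
    and 30 m yield maps and kriging variance as ASCII grids, descriptive /
    variogram / cross-validation / class JSON) and a ``reports/`` directory
    with the cross-harvest correlation matrix, CVI-yield correlations and
    per-image regressions (JSON + aligned text), plus ``run_manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg["seed"])
    spec = _field_spec(cfg)
    kcfg = _kriging_config(cfg)
    which = cfg.get("yield_column", "dry")
    factor = int(cfg["aggregate_factor"])
    vi_cfg = cfg["vi"]
    results: dict = {"harvests": {}}

    geometry = grid_for_field(spec)
    mask = make_pivot_mask(spec, geometry)
    target = RasterGrid(np.full(mask.shape, np.nan), mask.mask,
                        mask.x0, mask.y0, mask.pixel)

    maps30: dict[str, RasterGrid] = {}
    harvest_ids = sorted(data.points)
    for hid in harvest_ids:
        hdir = out / f"harvest_{hid}"
        hdir.mkdir(exist_ok=True)
        pts = data.points[hid]
        t0 = time.time()
        try:
            write_yield_points(pts, hdir / "points.csv")
            stats = describe(pts, which=which)
            _write_json(stats.to_dict(), hdir / "descriptive_stats.json")
            manifest.add(f"harvest{hid}/describe", t0, n_points=len(pts),
                         n_dropped=pts.n_dropped)

            t0 = time.time()
            emp = empirical_variogram(
                pts, lag_width=cfg["variogram"]["lag_width"],
                max_lag=cfg["variogram"]["max_lag"], which=which,
            )
            model = fit_variogram(emp, seed=child_seed(cfg["seed"], f"harvest{hid}/fit"))
            _write_json(model.to_dict(), hdir / "variogram_model.json")
            manifest.add(f"harvest{hid}/variogram", t0, form=model.form)

            t0 = time.time()
            est, var = ordinary_kriging(pts, model, target, kcfg, which=which)
            write_ascii_grid(est, hdir / "yield_10m.asc")
            write_ascii_grid(var, hdir / "kriging_variance_10m.asc")
            cv = cross_validate(pts, model, kcfg, which=which)
            _write_json(cv.to_dict(), hdir / "cross_validation.json")
            manifest.add(f"harvest{hid}/kriging", t0, n_cells=int(est.mask.sum()))

            t0 = time.time()
            est30 = aggregate_to_grid(est, factor)
            write_ascii_grid(est30, hdir / f"yield_{int(est30.pixel)}m.asc")
            classes = classify_yield(est30, tuple(cfg["classes"]))
            _write_json(classes.to_dict(), hdir / "yield_classes.json")
            manifest.add(f"harvest{hid}/aggregate_classify", t0)
            maps30[f"harvest_{hid}"] = est30
            results["harvests"][hid] = {
                "stats": stats, "model": model, "cv": cv, "classes": classes,
                "map10": est, "map30": est30,
            }
        except Exception as exc:
            manifest.add(f"harvest{hid}/FAILED", t0, error=str(exc))
            _write_json(manifest.to_dict(), out / "run_manifest.json")
            raise RuntimeError(f"pipeline failed in harvest {hid}: {exc}") from exc

    reports = out / "reports"
    reports.mkdir(exist_ok=True)

    # cross-harvest spatial correlation (with the seasonal total map)
    t0 = time.time()
    corr = correlation_matrix(maps30, include_total=len(maps30) >= 2)
    _write_json(corr.to_dict(), reports / "harvest_correlations.json")
    rows = [[""] + corr.names] + [
        [corr.names[i]] + [float(corr.r[i, j]) for j in range(len(corr.names))]
        for i in range(len(corr.names))
    ]
    _write_text_table(rows, reports / "harvest_correlations.txt")
    manifest.add("correlation_matrix", t0, n_grids=len(corr.names))
    results["correlations"] = corr

    # vegetation indices, CVIs, and their correlation with yield
    have_scenes = any(data.scenes.get(h) for h in harvest_ids)
    if have_scenes:
        t0 = time.time()
        cvi_rows = []
        cvi_report: dict = {}
        regressions: list[dict] = []
        kinds = [VIKind(k, L=vi_cfg.get("savi_L", 0.5)) for k in vi_cfg["kinds"]]
        cvis_by_kind: dict[str, dict[str, RasterGrid]] = {k.name: {} for k in kinds}
        for hid in harvest_ids:
            scenes = data.scenes.get(hid) or []
            if not scenes:
                continue
            hdir = out / f"harvest_{hid}"
            ymap = maps30[f"harvest_{hid}"]
            for kind in kinds:
                vis = [compute_vi(sc, kind) for sc in scenes]
                cvi = compute_cvi(vis, rule=vi_cfg.get("cvi_rule", "sum"))
                write_ascii_grid(cvi, hdir / f"cvi_{kind.name.lower()}.asc")
                cvis_by_kind[kind.name][f"harvest_{hid}"] = cvi
                r, p, n = correlate_grids(cvi, ymap)
                cvi_report.setdefault(kind.name, {})[f"harvest_{hid}"] = {
                    "r": r, "p": p, "n": n,
                }
                cvi_rows.append([kind.name, hid, float(r), float(p), n])
            for i, sc in enumerate(scenes, start=1):
                row = {
                    "harvest": hid,
                    "date": str(sc.date),
                    "crop_age_days": sc.crop_age_days,
                    "stage": sc.stage,
                }
                for name in ("NIR", "SAVI", "NDVI"):
                    kind = VIKind(name, L=vi_cfg.get("savi_L", 0.5))
                    res = regress_yield_on_index(ymap, compute_vi(sc, kind))
                    row[f"r2_{name.lower()}"] = res.r2
                regressions.append(row)
        # CVI vs total yield
        if len(maps30) >= 2:
            shared = np.logical_and.reduce([g.mask for g in maps30.values()])
            ref = next(iter(maps30.values()))
            tot = np.where(
                shared, sum(np.where(g.mask, g.values, 0.0) for g in maps30.values()), np.nan
            )
            total_map = RasterGrid(tot, shared, ref.x0, ref.y0, ref.pixel, units="t/ha")
            for kind in kinds:
                per_h = list(cvis_by_kind[kind.name].values())
                if len(per_h) == len(maps30):
                    season = compute_cvi(per_h, rule=vi_cfg.get("cvi_rule", "sum"))
                    r, p, n = correlate_grids(season, total_map)
                    cvi_report.setdefault(kind.name, {})["total"] = {"r": r, "p": p, "n": n}
        _write_json(cvi_report, reports / "cvi_yield_correlations.json")
        if cvi_rows:
            _write_text_table(
                [["CVI", "harvest", "r", "p", "n"]] + cvi_rows,
                reports / "cvi_yield_correlations.txt",
            )
        _write_json(regressions, reports / "image_regressions.json")
        if regressions:
            _write_text_table(
                [["harvest", "date", "age", "stage", "R2_NIR", "R2_SAVI", "R2_NDVI"]]
                + [
                    [r["harvest"], r["date"], r["crop_age_days"], r["stage"],
                     float(r["r2_nir"]), float(r["r2_savi"]), float(r["r2_ndvi"])]
                    for r in regressions
                ],
                reports / "image_regressions.txt",
            )
        manifest.add("vegetation_indices", t0, n_kinds=len(kinds))
        results["cvi_correlations"] = cvi_report
        results["regressions"] = regressions

    # harvest summary report (descriptive stats + variogram + classes)
    summary = {
        str(hid): {
            "descriptive": results["harvests"][hid]["stats"].to_dict(),
            "variogram": results["harvests"][hid]["model"].to_dict(),
            "cross_validation": results["harvests"][hid]["cv"].to_dict(),
            "classes": results["harvests"][hid]["classes"].to_dict(),
        }
        for hid in harvest_ids
    }
    _write_json(summary, reports / "harvest_summary.json")

    _write_json(manifest.to_dict(), out / "run_manifest.json")
    results["maps30"] = maps30
    manifest.results = results  # in-memory artifacts for programmatic callers
    return manifest


def simulate_study(cfg: dict | None = None, out_dir: str | Path = "study_out",
                   seed: int | None = None) -> RunManifest:
    """Generate the synthetic study inputs and run the full pipeline."""
    if cfg is None:
        cfg = default_study_config(seed if seed is not None else 0)
    elif seed is not None:
        cfg = {**cfg, "seed": seed}
    data = synthesize_study_data(cfg)
    manifest = run_pipeline(cfg, data, out_dir)
    manifest.results["truth"] = data
    return manifest
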