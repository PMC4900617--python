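"""Vegetation indices from an emulated satellite scene and their CVI.

Synthesizes two 30 m reflectance scenes over a yield surface (NIR coupled
to yield with a known correlation), computes NDVI / SAVI / NIR, accumulates
them into a cumulative index for the cycle, and correlates each with yield.
"""

from pivotyield import (
    BandCoupling,
    BandCouplingModel,
    FieldSpec,
    GRFParams,
    aggregate_to_grid,
    compute_cvi,
    compute_vi,
    correlate_grids,
    simulate_yield_surface,
    synthesize_scene,
)

spec = FieldSpec(radius=273.5, pixel_size=10.0)
surface = simulate_yield_surface(
    spec, GRFParams("spherical", 0.0, 1.2, 120.0, mean=3.0, seed=7)
)
surface30 = aggregate_to_grid(surface, 3)
sigma = surface30.masked_values().std()

bands = dict(BandCouplingModel().bands)
noise = 0.05
bands["NIR"] = BandCoupling(0.2, BandCouplingModel.slope_for_r(0.69, noise, sigma), noise)
implied = BandCouplingModel.implied_r(bands["NIR"].slope, noise, sigma)
print(f"NIR coupling designed for r = {implied:.2f} with yield (sd {sigma:.2f} t/ha)")

scenes = [
    synthesize_scene(surface30, BandCouplingModel(bands=bands, seed=s),
                     date=d, crop_age_days=a, stage=st)
    for s, d, a, st in [(1, "2013-12-21", 16, "Vegetative"),
                        (2, "2014-01-22", 48, "Vegetative")]
]

for kind in ("NIR", "SAVI", "NDVI"):
    vis = [compute_vi(sc, kind) for sc in scenes]
    for sc, vi in zip(scenes, vis):
        r, p, n = correlate_grids(vi, surface30)
        print(f"  {kind:>4} {sc.date} (age {sc.crop_age_days:2d} d): r = {r:+.2f}"
              f" (p = {p:.1e}, n = {n})")
    cvi = compute_cvi(vis, rule="sum")
    r, p, n = correlate_grids(cvi, surface30)
    print(f"  {kind:>4} cumulative over {len(vis)} dates:  r = {r:+.2f}")
print("-> the cumulative index is less noisy than single dates, so its")
print("   correlation with yield is at least as strong as the per-date ones.")
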