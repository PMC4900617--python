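# pivotyield

Geostatistical yield mapping and vegetation-index analysis for center-pivot
hay fields.

Forage growers increasingly harvest with baler-mounted yield monitors that
record a georeferenced wet/dry yield and moisture reading at every bale —
roughly 2,000 points per cut on a typical 23.5 ha pivot circle. `pivotyield`
turns those point files into kriged yield maps, quantifies how strongly the
yield is spatially structured, and relates the maps to multispectral
satellite observations (Landsat-style 30 m surface reflectance) through
vegetation indices and their per-cycle cumulative sums. It is a library
first (plus a thin `pivotyield` CLI for the config-driven pipeline), aimed
at precision-agriculture researchers and agronomists who want the whole
chain — variography, block kriging, index math, correlation/regression
reporting — reproducible and testable without GIS point-and-click steps.

Because real monitor files and imagery are rarely shareable, the package
ships a first-class synthetic generator: Gaussian random fields with known
nugget/sill/range over a circular pivot mask, concentric baler-track
sampling, and a linear band emulator whose NIR–yield correlation is known
in closed form. Every stage of the analysis is validated against that
known ground truth.

## The model

Yield `Z(x)` is treated as a regionalized variable. Its spatial structure
is summarized by the empirical semivariogram

    γ(h) = 1/(2N(h)) Σ [Z(x_i) − Z(x_i + h)]²

over the `N(h)` point pairs separated by lag `h`. A permissible model with
nugget `C₀`, partial sill `C` and range `a` is fitted by pair-count-weighted
least squares, choosing between

    spherical:    γ(h) = C₀ + C·(1.5 h/a − 0.5 (h/a)³)   for h ≤ a, else C₀ + C
    exponential:  γ(h) = C₀ + C·(1 − e^(−3h/a))          (practical range)

by residual sum of squares (R² reported alongside). The structural
proportion `C/(C₀+C)` measures how much of the variance is spatially
organized. Yield maps come from ordinary block kriging: for each 10 m
block `B`, weights `λ` solve

    Σ_j λ_j γ(x_i, x_j) + μ = γ̄(x_i, B),   Σ λ_j = 1

and `Ẑ(B) = Σ λ_i Z(x_i)`, with the kriging variance reported per cell and
accuracy checked by leave-one-out cross-validation. Maps are aggregated to
the 30 m satellite grid for zonal comparison with the indices

    SR = NIR/R,  NDVI = (NIR−R)/(NIR+R),  SAVI = (NIR−R)(1+L)/(NIR+R+L),
    EVI = 2.5(NIR−R)/(NIR+6R−7.5B+1),  GRVI = (G−R)/(G+R),
    GNDVI = (NIR−G)/(NIR+G),  LSWI = (NIR−SWIR1)/(NIR+SWIR1)

plus the raw NIR band, and their cumulative (per-cycle) sums (CVIs).
Reporting covers descriptive statistics with skewness/kurtosis standard
errors, yield-class area tables, Pearson correlation matrices with
t-distribution p-values, and per-image yield~index regressions.

## Worked example

`examples/02_variogram_kriging.py` simulates one harvest (spherical
structure, sill 2.21 (t/ha)², range 120 m, monitor noise variance 0.67) and
runs the variography–kriging–classification chain:

```
fitted model: spherical
  nugget Co = 0.42 (t/ha)^2, sill Co+C = 2.40, range a = 107 m
  R^2 = 0.979, structural proportion C/(Co+C) = 0.83
block kriging on 10 m blocks: 2361 cells, mean kriging sd 0.40 t/ha
leave-one-out: r(pred, obs) = 0.81, RMSE = 0.88 t/ha, mean error = +0.000
yield classes on the 30 m map (area ha / share %):
    < 2 t/ha :  11.1 ha  ( 42.7 %)
    2-3 t/ha :   6.4 ha  ( 24.7 %)
    3-4 t/ha :   5.8 ha  ( 22.6 %)
    4-5 t/ha :   2.4 ha  (  9.4 %)
    > 5 t/ha :   0.2 ha  (  0.7 %)
  average yield 2.37 t/ha over 25.9 ha
```

The fitted nugget/sill/range land near their generating values; the
structural proportion says ~83% of the yield variance is spatially
organized, so the class map delineates real productivity zones rather than
noise. The other examples cover field simulation (`01`), index/CVI math
(`03`) and the full four-harvest study (`04`), e.g.

```sh
python examples/04_full_study.py     # or: pivotyield simulate --seed 1 --out-dir study_out
```

which prints the cross-harvest correlation matrix of the kriged maps
(pairwise r ≈ 0.72–0.82 at the default latent share of 0.8, with the
seasonal total-yield column correlating highest, r ≈ 0.84–0.93).

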