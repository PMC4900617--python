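# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## Regionalized-variable model

Dry hay yield (t/ha) at baling locations is modeled as a second-order
stationary random field. The empirical semivariogram is the classical
Matheron estimator: half the mean squared difference of all unordered
point pairs whose separation falls in a lag bin. Defaults follow common
variography practice where the user gives none: lag width = 2× the median
nearest-neighbor distance, maximum lag = half the larger coordinate span.
Bins with zero pairs are carried but flagged (NaN semivariance).

Two permissible isotropic models are supported, with the exponential in
the *practical range* convention (`γ` reaches 95% of the sill at `h = a`,
i.e. `exp(−3h/a)`), so the fitted range is directly comparable with the
spherical range. Fitting is nonlinear least squares (trust-region, bounds
`C₀, C ≥ 0`, `a > 0`) on the binned semivariances weighted by pair counts
`N(h)`; the reported RSS is that weighted objective and is what model
selection minimizes, while R² is the plain coefficient of determination of
fitted vs empirical semivariance. Initialization is `C₀ = min γ`,
`C = max γ − C₀`, `a` = first lag reaching 95% of `max γ`, with two
jittered restarts (seeded) against local minima. When RSS and R² rank the
forms differently, RSS wins.

Form discrimination depends on resolving the near-origin curvature:
on small fields (a 23.5 ha circle with a 120 m range) exponential and
spherical fits are frequently statistically indistinguishable; the
selection-consistency tests therefore use a larger simulated field
(~100×100 cells) and a maximum lag of 2.5× the range.

## Ordinary block kriging

Each target block (10 m × 10 m by default, discretized 4×4; one
discretization point reproduces point kriging exactly) is predicted from
its `k = 16` nearest observations within a search radius of 1.5× the
fitted range (never below 50 m), solving the standard ordinary-kriging
system with the unbiasedness constraint. Point-to-block and block-within-
block semivariances are discretization averages.

Two conventions worth stating:

* The semivariance used on kriging right-hand sides is right-continuous at
  zero (`γ → C₀` as `h → 0⁺`), so prediction at a data location smooths
  whenever the nugget is positive and is exact exactly when `C₀ = 0`. On
  the left-hand side, coincident data are impossible because duplicated
  coordinates are averaged before solving (duplicates are kept for
  variography, where they inform the nugget).
* Kriging variances are clipped at zero; anything below −10⁻⁶ is logged as
  a numerical warning rather than silently clipped.

Leave-one-out cross-validation re-predicts every point by point kriging
from its neighbors and reports mean error, RMSE and r(predicted, observed).

## Synthetic study conditions

The generator emulates a 23.5 ha center-pivot circle (radius 273.5 m) on a
10 m analysis grid. Yield surfaces are stationary Gaussian random fields:
exact Cholesky factorization of the full covariance is the reference path
for grids up to 4096 cells; larger grids use circulant-embedding FFT
synthesis (negative spectral mass is clipped; the clipped fraction is
logged if above 10⁻³). Both paths are driven by one `numpy` Generator seed
and are bit-reproducible.

The four-harvest study (`default_study_config`) uses per-harvest means
2.32 / 2.45 / 2.86 / 4.01 t/ha, nugget–sill pairs (0.02, 0.07),
(0.54, 1.47), (0.67, 2.88), (1.43, 4.25) (t/ha)², an exponential form for
the first harvest and spherical for the rest, and the 18-image winter
calendar (dates, crop ages, phenological stages) of an October–May alfalfa
season. Choices the study conditions do not pin down, made once:

* **Range = 120 m** for all harvests. The published ranges for this kind of
  field are unit-ambiguous (values of 0.01–0.09 with no unit are
  implausible in meters); 120 m is a plausible structured scale for a
  547 m-diameter pivot and is not treated as a reproducible quantity.
* **Track geometry**: concentric circular passes 12 m apart (baler swath),
  one record every 10 m, random angular phase per pass — ≈1,980 points per
  harvest, inside the observed 1,677–2,677 per-harvest range and near the
  nominal 2,000.
* **Nugget placement**: the monitor's reading error plays the nugget — the
  simulated surfaces carry only the structured variance, and i.i.d. noise
  of variance `C₀` is added per record at sampling. (A cell-level nugget
  would be partially averaged away by the bilinear sampling and is not how
  a physical monitor error arises.)
* **Latent share 0.8**: each harvest's structured field is
  `√0.8·L₀ + √0.2·L_h` (shared latent `L₀`, independent `L_h`), giving
  pairwise map correlations around 0.7–0.85 — the strongly-correlated
  regime observed in multi-cut yield mapping. Unit fields are conditioned
  to zero mean over the pivot circle so each harvest's realized field mean
  equals its specified mean.
* **Band coupling**: each reflectance band is linear in yield plus i.i.d.
  Gaussian noise, clipped to [0, 1] (NIR slope +0.045/(t/ha), red negative;
  NIR noise 0.055 so the implied per-scene NIR–yield correlation is ≈0.7 at
  a yield sd of 1.2 t/ha, matching the strongest single-band relationships
  reported for alfalfa). The closed form
  `r = sσ_y/√(s²σ_y² + τ²)` for slope `s`, yield sd `σ_y`, noise sd `τ` is
  exposed (`implied_r`, `slope_for_r`) and verified by test.

What the emulator deliberately omits: phenology-dependent reflectance
(bloom-stage saturation, dormancy), radiative transfer, anisotropy,
harvest-to-harvest changes in spatial structure shape, and GPS/positional
error. Consequently, cumulative indices are *cleaner* than single dates
here (i.i.d. scene noise averages out), whereas in real seasons
stage-dependent biology can break that monotonicity; passing tests
demonstrate the correctness of the computational chain, not the field
ecology.

## Reporting layer

Descriptive statistics use `n−1` variance, adjusted Fisher–Pearson
skewness, adjusted excess kurtosis, and the classical normal-theory
standard errors `SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3)))`,
`SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5)))` (≈0.06 and 0.12 at
n ≈ 1,700). Yield classes are left-closed/right-open with open extremes
(breaks 2, 3, 4, 5 t/ha by default); areas are unmasked-cell counts times
cell area. Raster correlations are Pearson over shared unmasked cells with
two-tailed p from the t-distribution on `n−2` degrees of freedom, where
`n` is the shared 30 m cell count (~260–290 for this field) with no
spatial-autocorrelation adjustment and no multiple-testing correction.
The "total yield" map is the per-cell sum of the per-harvest kriged maps.
Simple regression reports OLS slope/intercept and `R² = r²`.

Cumulative vegetation indices accumulate per-pixel **sums** over all scene
dates within a cycle (per-date mean available as a config option); the
harvest-day image belongs to its cycle. SAVI uses `L = 0.5` by default
(standard intermediate-cover value), configurable. Negative reflectances
are clipped to 0 (counted and logged); zero-denominator pixels are masked
in the output, never raised.

## I/O and geometry conventions

All geometry is projected meters; grids are north-up with the origin at
the upper-left corner and cell centers at `origin + (i+0.5)·pixel`.
Rasters serialize as ESRI ASCII grid (text, nodata −9999), points as
RFC-4180 CSV (XLSX accepted on input). Longitude/latitude inputs must pass
through the explicit local flat-Earth projection (centimeter-accurate at
sub-kilometer extents); degree-like coordinates presented as meters fail
loudly. Aggregation to the 30 m grid is the mean of unmasked fine cells,
masking a coarse cell only when all constituents are masked; shapes not
divisible by the factor are padded with masked cells and logged.

## Problem sizes and determinism

Default analysis sizes: ~2,350 10 m cells inside the circle, ~1,980 points
per harvest, 16-neighbor kriging solves per cell, LOOCV over all points —
the full four-harvest study runs in tens of seconds on one CPU; the
parameter-recovery experiment fits 20 independent ~7,850-cell fields
subsampled to 2,500 points each. One global seed fans out to per-stage
child seeds by SHA-256 hashing of stage names (all below 2³¹), so adding a
stage never perturbs another stage's stream; reports regenerated with the
same seed are byte-identical.

## Known limitations

* Isotropic variograms only; no universal/co-/indicator kriging.
* The variogram fit weights by pair count; generalized-least-squares
  (correlated-bin) fitting is not attempted.
* The p-values ignore spatial autocorrelation of the 30 m cells, matching
  standard zonal-analysis practice but overstating effective sample size.
* The local projection is a single flat-Earth tangent plane — adequate for
  one field, wrong for regional mosaics.
* The band emulator is statistical, not physical: it cannot reproduce
  stage-dependent index behavior or saturation at high leaf area.
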