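# Methods

This note documents the models, the parameter choices that matter, the
synthetic-data design, and the numerical details behind `thermozone`.

## Thermal indices and milk loss

The Temperature–Humidity Index is computed from annual mean air temperature
and wind speed; the default registered formula is

    THI = 6.3952 + 0.08964·Tair + 0.01018·Ws²

with the wind term read as wind speed squared (consistent with the units
structure of wind-adjusted THI equations). The formula is deliberately
pluggable: published THI variants differ in their drivers and scaling, and
this particular linear form yields index values near 8–9 at tropical annual
means, an order of magnitude below the 70–90 scale on which the stress
categories and the milk-loss regression are defined. Analyses whose
downstream stages depend on the 70–90 scale should register a formula on
that scale (the test suite and examples register `scaled_tair` for this
purpose); every pipeline output records the formula that produced it, and
the milk-loss regression accepts THI directly so its results never depend
on the index formula choice.

The decrease in milk production for a cow of potential production NP
(kg day⁻¹, under thermal comfort) is the linear regression

    DMP = −1.075 − 1.736·NP + 0.02474·NP·THI

DMP is linear in THI with slope 0.02474·NP and crosses zero at
THI ≈ 74.5 for NP = 10 and ≈ 72.6 for NP = 25: higher-yielding cows start
losing milk earlier and lose it faster. The raw regression value is kept
for diagnostics; the reported loss is clamped at zero because a production
decrease cannot be negative.

Category boundaries are implemented exactly as stated by their sources:
LWSI normal/alert/danger/emergency at 74/79/84 (normal inclusive at 74,
danger inclusive at 79, emergency inclusive at 84); dairy stress onsets at
72/79/89 treated as inclusive lower bounds; CV dispersion bands at 12% and
24% with the medium band closed on both ends. Every classifier partitions
the real line — each finite input maps to exactly one class.

## Standardized Precipitation Index

Annual precipitation totals are fitted with a two-parameter gamma
distribution by maximum likelihood (scipy's constrained MLE with the
location fixed at zero). Zero totals — rare on the annual scale but
possible — enter through the mixed distribution H(x) = q₀ + (1 − q₀)·F(x),
the standard McKee-style treatment; SPI = Φ⁻¹(H(x)). Fitting requires at
least 10 positive values with nonzero variance. The CDF argument is
clipped to [1e−12, 1 − 1e−12] so SPI stays finite at the sample extremes.

SPI classification uses contiguous bands at the cut points
(−2, −1, −0.5, 0.5, 1, 2). The printed band tables in common use leave
micro-gaps between, e.g., −0.99 and −1.00; the implementation closes them
so every value classifies, with boundary membership following the printed
convention (−1 is Very Dry, −0.5 Moderately Dry, 0.5 Moderately Wet, and
±2 belong to the extreme classes).

Regional aggregation computes each region's annual series as the
region-mean precipitation and fits the SPI per region; the domain-wide
series uses the global mean. SPI is invariant to rescaling precipitation by
a positive constant (the gamma scale absorbs it), which the tests assert.

## Geostatistics

**Distances.** Three metrics are supported and recorded in every report:
planar degrees (identity), equirectangular meters (local projection about
the domain's mean latitude; the default for geographic data, accurate to a
fraction of a percent at state scale), and great-circle (3-D spherical
embedding whose Euclidean chord differs from the arc by < 0.1% below
~500 km). All downstream routines consume the resulting Euclidean
coordinates, so one code path serves all metrics. When prediction targets
are projected, the sample mean latitude is reused as the projection
reference so samples and targets share one frame.

**Semivariogram.** Pairs are binned into `n_lags` equal-width bins (default
12) up to `max_dist` (default half the maximum pairwise distance — the
conventional cutoff beyond which lags are poorly populated). Empty bins are
reported with N = 0 and NaN semivariance. Model fitting minimizes the
pair-count-weighted squared error via bounded least squares with a
three-point multi-start on the range; weights N(h) make well-populated lags
count more. A fit whose partial sill collapses below 10⁻⁶ of the sill emits
a no-spatial-structure warning (pure nugget).

The three families use the practical-range convention (factor 3 in the
exponent), so the exponential and gaussian models reach ≈ 95% of the sill
at h = a while the spherical reaches it exactly. γ(0) = 0 exactly; the
nugget is a discontinuity at the origin.

**Kriging.** Ordinary kriging solves the augmented system with a Lagrange
multiplier for the unbiasedness constraint Σλ = 1; the kriging variance is
λᵀγ₀ + μ (clipped at zero against roundoff). Prediction is local with the
16 nearest neighbors by default — the usual scalability compromise — with a
global mode (`n_neighbors=None`) for oracle-style verification. Equidistant
neighbors at the cutoff are ordered by ascending sample index, making
results deterministic. Duplicate sample locations with a zero nugget make
the system singular; the error message says so and suggests the remedy.

**Cross-validation and selection.** Leave-one-out prediction uses the same
local neighborhood as production kriging. The five metrics follow the
ArcGIS-style definitions; note "MSE" here is the *mean standardized error*
(a mean of standardized residuals, not of squares). σ₁ is the kriging
standard error of the held-out prediction. Model selection formalizes the
usual verbal reading of these diagnostics into a deterministic rule:
minimize |RMSSE − 1|, break ties (within 10⁻⁶) by smaller |RMSE − ASE|,
then smaller RMSE, then the fixed order spherical → exponential → gaussian.
The full ranking table is attached to every selection so a reviewer can see
how close the call was.

**Spatial dependence.** DSD = 100·nugget/total sill, classed strong
(< 25%), moderate (25–75%, boundaries inclusive), weak (> 75%). The ratio
and the class are invariant to rescaling the variogram.

## Synthetic climate fields

The generator emulates the statistical structure of a gridded annual
climatology over a tropical state-sized domain — not any particular
region's true climatology, orography, or teleconnections. Defaults encode
the study conditions of the analysis the package implements:

- domain ≈ 5.7° × 9.1° (a Maranhão-shaped box), years 2012–2023;
- mean Tair 27.3 °C with a +0.15 °C per degree-latitude gradient (warmer
  toward the equator) plus a spherical Gaussian random field (nugget 0.01,
  partial sill 0.35, range 1.5°, matching the 0.30–0.43 sills typical of
  annual THI fields at this scale);
- wind speed as the exponential of an independent standardized Gaussian
  field (median 1.4 m s⁻¹, log-scale 0.25), keeping the bulk of values in
  the 0.7–2.8 m s⁻¹ band with structural positivity;
- annual precipitation gamma-distributed with shape 30 and scale 54.1 mm
  (mean 1623 mm, CV ≈ 18%, typical of annual totals at this latitude);
- drought years {2012, 2015, 2016, 2023} with precipitation multiplier 0.6
  and +0.5 °C temperature offset.

Gaussian random fields are synthesized by dense Cholesky factorization of
C(h) = sill − γ(h) with the full sill on the diagonal, i.e. the nugget is
realized as independent white noise per location. This is exact but O(n³);
a single field is limited to ~5000 points (a guard rejects more). A jitter
of 10⁻¹⁰·sill stabilizes the factorization; if it still fails the model/
location combination is rejected as not positive definite.

Randomness is organized as one child `SeedSequence` stream per
(year, variable), so identical configs are bit-identical and adding or
removing a year never perturbs other years' draws.

What the generator does *not* emulate: temporal autocorrelation between
years, orographic structure, coastal effects, ENSO-style interannual
regimes, anisotropy, or covariance between temperature and precipitation
beyond the shared drought flag. Tests passing on synthetic fields therefore
demonstrate the correctness of the estimators and the pipeline plumbing,
not the realism of any particular regional map.

## Pipeline choices

- **Index-then-krige (default):** THI and DMP are computed per point and
  then interpolated, matching how zoning maps are usually presented. A
  krige-then-index mode interpolates Tair and wind first and derives the
  indices on the grid; in that mode the reported error surface is the
  temperature kriging error (a driver-uncertainty proxy, since the index
  error no longer has a closed form).
- **Output grid:** bounding box of the input points at their native spacing
  (median spacing of the unique coordinates), configurable.
- **Degenerate layers:** a spatially constant field has an undefined
  variogram; the pipeline short-circuits to constant surfaces with zero
  standard error rather than failing.
- **Area fractions** are equal-weight cell fractions of the classified THI
  surface per scheme and sum to 1 by construction.
- **Scenario layers** (pathway × horizon) run through exactly the same
  per-layer workflow as historical years; pathway and horizon vocabularies
  are closed (RCP4.5/RCP8.5; short/mid/long = 2011–2040/2041–2070/
  2071–2100).
- **Rasters** are written as ESRI ASCII grids (plain text, GIS-readable)
  with a companion standard-error band; tables as CSV plus a JSON run
  summary that echoes the formula, metric, lag design and selections —
  exactly the knobs that are usually left implicit.
- **SPI stage** is skipped with a logged warning when the record is too
  short to fit (fewer than 10 years), rather than failing the whole run.

## Test design and problem sizes

Stochastic verifications run at desk scale: variogram/sill recovery uses
2000-point fields with the range set to 0.15 of the unit-domain side so a
realization carries many correlation lengths (recovery experiments are
ill-posed when the range approaches the domain size); RMSSE calibration
uses 500-point leave-one-out at the true model; metric definitions are
checked against explicit-loop recomputation to 10⁻¹⁰; kriging systems are
checked against a brute-force dense solve to 10⁻¹⁰. Property-based tests
(hypothesis, derandomized) cover monotonicity, partition, and invariance
claims.

## Known limitations

- The default THI formula scale issue described above: it is kept verbatim
  as the registry default, but regional stress/loss mapping needs a formula
  on the 70–90 scale.
- Isotropic variograms only; no anisotropy, co-kriging, or universal
  kriging (the workflow assumes intrinsic stationarity).
- Annual accumulation only for SPI (the window is configurable in
  principle, but no sub-annual machinery is provided).
- Dense-Cholesky field synthesis caps synthetic fields at ~5000 points;
  larger grids must be assembled from tiles or generated by other means.
- The equirectangular metric degrades on domains spanning tens of degrees
  of latitude; use the great-circle metric there.
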