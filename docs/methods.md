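# Methods

This note records the model, the estimation choices, and the numerical
decisions behind `airlur`, in the order the pipeline runs.

## 1. Monitor QC

Input is a per-site time series of hourly or daily measurements; absent
timestamps are missing data. Rules, applied in order:

- **Daily validity.** A daily-cadence record is valid per se; an
  hourly-cadence day is valid only with ≥ 18 of 24 hourly values.
- **Schedule classification.** The gaps (in days) between consecutive
  reported days are tallied; the modal gap is snapped to the nearest of
  {1, 3, 6} giving the schedules *everyday*, *1-in-3*, *1-in-6*.
- **Completeness.** Valid-day minima per schedule: 244 / 61 / 41.
- **Maximum gap.** No measurement-free run longer than 45 days. Runs are
  measured inside the calendar year and *include* the stretches between
  January 1 and the first measurement and between the last measurement and
  December 31 — a design decision: a site that starts reporting in March has
  no data for a 60-day stretch of the year regardless of whether a
  measurement brackets it on both sides.
- **O3.** Season May 1 – September 30 (153 days); the daily metric is the
  maximum over the 17 8-hour windows starting 00:00–16:00 of the mean of the
  hours present, a window being valid with ≥ 6 of its 8 hours; a site-year
  needs ≥ 115 valid days (75 % of the season, rounded up).

Annual averages are square-root transformed before modelling
(`z = sqrt(y)`); back-transformation clamps at zero (`y = max(z, 0)²`),
keeping concentrations non-negative.

## 2. Geographic covariates

Buffer radii: 100 m, 500 m, 1 km, 5 km, 15 km (bounds 50 m–15 km enforced).
Per category:

- **Line length in a disk** (roads, major roads): each segment is clipped to
  the disk analytically — the intersection parameters solve a quadratic in
  the segment parameter — so chord lengths are exact to machine precision
  rather than polygon-approximation accuracy.
- **Point counts** (emission sources) and **distance to nearest source**
  (metres).
- **Raster aggregation** (developed-land fraction, population): cell values
  are weighted by the area of cell ∩ disk. The disk is shapely's polygonal
  circle (`quad_segs=64`) and its *own* polygonal area is the denominator,
  so a fully covered buffer gives a weight of exactly 1.
- **Population apportionment**: block/cell population times the covered
  area fraction.
- **Satellite grid sampling**: the cell containing the site, with a
  nearest-cell fallback at the domain edge. Cells are half-open — a point on
  a shared edge belongs to the lower-left cell (`ix = ceil((x−x₀)/Δ) − 1`).
- Site coordinates (km) enter as two further candidates.

Coordinates: a fixed affine mapping between km offsets and lon/lat about
(−98.35°, 39.50°) with the per-degree lengths at that latitude. Distances are
Euclidean in km by default; a great-circle (haversine, R = 6371 km) metric is
available throughout.

## 3. Variable selection

Forward selection by the partial F statistic. Step 1 is equivalent to
picking the largest |Pearson correlation|. Later steps residualise the
remaining candidates against the selected set (Gram–Schmidt deflation), so
each sweep over m candidates is O(n·m). Ties break by variable name;
a perfect fit (F = +∞) is selectable; selection stops when no candidate
improves (F ≤ 0) or the requested count is reached. Constant and collinear
candidates (relative tolerance 1e-10) are skipped.

## 4. PLS + universal kriging

The selected variables are centred and scaled (ddof = 1) and compressed to
k = 2 (default) univariate-PLS scores; the first weight vector is
proportional to `X_centredᵀ y`, and k = rank reproduces OLS — both limits
are tested. The PLS core is scikit-learn's `PLSRegression` behind this
package's surface.

The kriging model on the sqrt scale is

    z(s) = β₀ + t(s)ᵀβ + Z(s) + ε(s),
    Cov[Z(s), Z(s′)] = σ² exp(−|s−s′|/φ),  Var[ε] = τ².

β is profiled out by GLS, and the profile (or REML) negative log-likelihood
is minimised over `log(τ², σ², φ)` with L-BFGS-B from four starts (three
variogram-motivated splits of the OLS residual variance plus a balanced
start). Box bounds address the likelihood ridge that appears when the range
is far below the site spacing (a tiny-range field is indistinguishable from
a nugget): φ ∈ [median nearest-neighbour distance, 3·max pairwise distance],
and both variances ∈ [1e-8, 1e2] × OLS residual variance. The variance
bounds are relative, so the fit is scale-equivariant (tested). Predictions
use the universal-kriging equations; the variance adds the
`uᵀ(FᵀΣ⁻¹F)⁻¹u` trend-uncertainty term. With τ² = 0 the predictor
interpolates the training data.

Models serialise to JSON (parameters, scalers, PLS weights, θ, training
data); reloading refits the GLS coefficients at the stored θ, which
reproduces β exactly.

## 5. Evaluation

10-fold CV; within each training fold the *entire* chain — forward
selection, PLS, covariance estimation — is refit, so no information leaks
from held-out sites (a leak test asserts an intentionally leaky evaluation
scores higher on noise). Fold schemes:

- **conventional** — seeded random permutation, balanced sizes;
- **clustered** — k-means on site coordinates (k = 10, `n_init = 50`,
  seeded). k-means replaces a hand-rolled farthest-point-seeded variant:
  deterministic given the seed and one less bespoke primitive.

Predictions are pooled across folds on the native scale. Metrics:
MSE-based R² about the 1:1 line, `1 − Σ(y−ŷ)²/Σ(y−ȳ)²` (negative when
predictions are worse than the mean), and sRMSE = RMSE / mean(y). On
spatially clustered networks, clustered CV is the harder test and
conventionally exceeds it — the acceptance suite checks this ordering.

## 6. Application

Block-centroid predictions (batched; batch size does not change results),
then population-weighted means at block group / tract / county from the
nested FIPS prefixes (5 / 11 / 12 digits). Aggregation is associative
(block → tract equals block → block group → tract) and conserves a constant
field exactly.

## 7. Synthetic generator

What it emulates: a square study domain with a few exponential urban foci;
population and developed-land rasters; road and major-road segments; point
emission sources near foci; a coarse smoothed "satellite" raster. The
ground-truth sqrt-scale field is a linear function of four physically
motivated covariates (log-population, source proximity, road proximity,
satellite) plus a Gaussian random field with known exponential covariance —
simulated lazily by conditional simulation with a coordinate-keyed cache, so
the field can be evaluated anywhere yet repeat queries are deterministic.
Monitoring series add seasonal and diurnal cycles, lognormal measurement
noise, schedule subsampling, missingness and optional planted long gaps.
Blocks are sampled population-weighted with valid nested FIPS codes.

What it does not emulate: real emission inventories or chemistry, terrain
and meteorology, spatially varying measurement error, multi-year trends, or
real census geography.

## 8. Limitations

- Exponential covariance only; no anisotropy, no nested structures.
- Exact (dense Cholesky) kriging: fine for thousands of sites, not millions.
- The affine coordinate mapping distorts over continental extents; the
  great-circle metric mitigates distance error but the projection of the
  synthetic landscape itself is idealised.
- Univariate PLS only (one pollutant at a time).
- Kriging standard errors are reported on the sqrt scale; no delta-method
  back-transformation is applied.
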