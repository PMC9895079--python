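# Methods

## Problem and model

`grazegrid` downscales county-level livestock census totals (standard
sheep units, SU) to a raster grid. The method assumes that (i) grazing
occurs only inside a suitability mask carved from the grassland extent,
(ii) grazing pressure depresses observed NDVI below its potential
(undisturbed) level, so the NDVI deviation field carries the within-county
spatial signal the census lacks, and (iii) the relationship between
grazing density and environmental covariates is smooth enough for a random
forest to transfer from aggregated training units to pixels.

### Disturbance prior

Per pixel, `D_i = NDVI_obs_i − NDVI_pot_i` is a length-T vector over the
time steps. With `u` and `cov` the mean and T×T covariance of `D` over all
valid pixels of the study area, the absolute disturbance index is the
Mahalanobis distance `AD_i = sqrt((D_i − u)ᵀ cov⁻¹ (D_i − u))`. The
population statistics are computed globally, not per county, so all
counties share one disturbance scale. Census totals are distributed
pixel-wise in proportion to raw AD (no rank transform), which conserves
each county's total by construction. Caveat: Mahalanobis distance is a
deviation measure, so pixels unusually *un*-grazed also score high; with
the right-skewed density distributions typical of extensive grazing
systems the bulk of pixels sits near `u` and AD behaves monotonically over
the mass of the distribution.

Numerical handling: pixels with any missing NDVI step are excluded from
both the statistics and the distribution; a covariance with condition
number above 1e12 is ridge-regularized with `λ = 1e-8·trace(cov)/T`
(logged); if all deviation vectors coincide, AD is 0 everywhere and no
inversion is attempted. Counties whose AD sum is zero fall back to uniform
weights; counties with a positive census but no masked pixels go to an
"undistributable" report instead of aborting.

### Cross-scale features

Within each county the distributed SU values are clustered by
agglomerative Ward linkage (1-D), with the group count k chosen to
minimize the Davies–Bouldin index over candidates k = 2…6 (capped at the
county's pixel count; ties go to the smaller k for parsimony). Group
centroid distance is the absolute difference of means; coincident
centroids make the index +inf, rejecting that k. Counties with fewer than
two pixels, or with no within-county structure, contribute a single row —
the traditional county mean — so the cross-scale table degenerates exactly
to the county table on homogeneous landscapes. Group covariates are
unweighted pixel means; categorical covariates take the mode.

### Partitioned random forest

The response is transformed through `ln(y + 1)` (the +1 offset admits
zero-density groups and is recorded in the model metadata). Samples are
split 3:1 into training and test sets with a fixed seed; held-out
R²/RMSE/MAE are recorded per submodel on the back-transformed scale.
Partitioned variants (M2, M4) route a row high iff its density
(response / pixel area, SU/hm²) strictly exceeds the threshold of its
grassland type — boundary values go low. Default thresholds: 0.43 (alpine
meadow), 0.35 (alpine steppe), 0.21 (alpine desert steppe) SU/hm²;
`theoretical_capacity_threshold(yield, utilization, intake, days)` derives
alternatives as `yield·utilization/(intake·days)` for other systems. A
partition with fewer than 8 rows triggers a documented fallback to the
single pooled model rather than fitting an unstable forest.

At prediction time the partition class of a pixel is unknown (its density
is what we are estimating), so a provisional estimate from the pooled
model is thresholded to choose the submodel — a deterministic rule. The
forests use 500 trees, default feature subsampling and a fixed seed; all
are configurable.

### Residual correction

For each county, `R_j = census_j/n_j − mean(su_raw)` is added to every
pixel. Since the additive shift can drive pixels negative, negatives are
clipped and the lost mass re-spread proportionally over positive pixels,
iterating to a 1e-9 relative tolerance — preserving both nonnegativity and
the county total. This step is why corrected grids agree with the census
at county level essentially exactly; county-level agreement metrics are
therefore reported on the *raw* model output, where they are informative.

### Validation metrics

R² is the one-minus-error-ratio form against census variance (it can be
negative; it is not a squared correlation). NSE applies the same form
along the time axis. MRE is the mean absolute relative county deviation in
percent; zero-census counties are excluded and counted.

## Synthetic landscape generator

The generator emulates the statistical structure the method assumes, not
any real geography:

* **County mosaic** — Voronoi tessellation of uniformly sampled seed
  pixels: contiguous, irregularly sized units.
* **Covariates** — Gaussian-smoothed white noise (σ = `spatial_range`,
  default 6 px), standardized; autocorrelation decays with distance.
* **Truth density** — `b0 + b1·x1 + b2·x2 + b3·x3 + b12·x1·x2`, clipped at
  0, with defaults (8, 14, 9, 6, 4) SU/pixel over the first three
  covariates; the clipping produces the right-skewed density real grazing
  shows, and the sparse form makes feature importances known. A yearly
  factor (default +4 %/yr) adds a temporal trend; pixel noise defaults to
  0.5 SU/pixel.
* **NDVI pair** — potential NDVI is a smooth field in [0.35, 0.85];
  observed = potential − `s·d/(d + d0)` (s = 0.25, d0 = 20 SU/pixel, a
  strictly increasing saturating deficit) plus small measurement noise,
  never exceeding potential on grazed pixels.
* **Census** — exact zonal sums of the truth, so conservation checks have
  a bit-exact reference.

Defaults (60×60 grid, 25 counties, 3 years, 6 covariates, pixel area
50 hm²) keep a full M1–M4 ladder run under ~10 s while leaving enough
counties and within-county pixels for the cross-scale machinery to matter.
What the generator does **not** emulate: wildlife herbivory confounding
the NDVI deficit, off-take and seasonal herd dynamics, census reporting
error, anisotropic terrain effects, and the estimation of potential NDVI
itself (consumed as an input). Passing tests therefore demonstrate the
mechanics and the relative ordering of the model variants, not real-data
accuracy levels.

## Design choices where the design was open

* Mean `u` and covariance for AD are global rather than per county (a
  common disturbance scale; per-county covariances would be poorly
  estimated for small counties).
* The dasymetric weight is raw AD; alternative weightings can be swapped
  in at the `dasymetric_distribute` call site.
* Clustering operates on the 1-D distributed SU values only (not the full
  covariate vector), per county.
* The partition is binary (below/above the type-specific threshold)
  yielding two submodels, with the three per-type thresholds doing the
  routing.
* Missing census years are ratio-scaled by the parent administrative
  series, with linear interpolation as the documented fallback; filled
  rows are provenance-flagged so users can substitute their own rule.
* Suitability cutoffs (default 5500 m elevation, 2 km town distance) are
  explicit required configuration, reported in the criteria log.

## Known limitations

* The M1–M4 ordering on synthetic data is a stochastic property: at the
  default landscape and seeds the cross-scale variants dominate clearly,
  but single-seed margins between M4 and M1 can be small on easy
  landscapes where county means already predict well.
* Rasters are plain lattices (TIFF without geo-tags); georeferencing,
  reprojection and resampling are out of scope and should be done upstream
  with a GIS stack.
* The partitioned model needs enough samples per partition; with few
  counties and no CSF enrichment (M2) it can underperform the pooled
  model.
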