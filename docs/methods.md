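# Methods

This note documents the models and procedures implemented in `hydromove`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Tracking data model

Fixes are hourly positions between 06:00 and 18:00 at a fixed UTC+02:00
offset (the activity period of the birds); "days" are local midnights.
Speed filtering is sequential-greedy: each fix is tested against the last
*retained* fix and dropped when the implied great-circle speed exceeds
150 km/h. Greedy filtering is deterministic, order-stable and idempotent;
a visual-inspection step has no algorithmic equivalent, so an optional
user-supplied exclusion list of fix indices stands in for it. Duplicate
timestamps keep the first row with a warning.

Age classes switch at 1 May (the start of the breeding season): a bird
tagged as a juvenile is juvenile until the first 1 May after tagging,
immature for the next two May-to-May years, and adult from the fourth year
onward; a bird tagged as an adult is adult throughout. The windows are
clipped to the tracking span and tile it exactly.

## Distances, daily metrics, Moving-Day threshold

All distances are haversine on a sphere of radius 6371.0088 km. At
residence-area scales the sphere-vs-ellipsoid error is below 0.5%, far
under the GPS error, and it keeps the oracle closed forms simple. The
daily metric is the maximum distance over all pairs of the day's fixes.
The displacement between the last fix of day *d* and the first fix of day
*d*+1 is "night movement" and is credited to day *d* (`effective
distance`); it applies only to consecutive calendar days — a data gap
contributes nothing. Days without fixes produce no record at all: absence
of data is not evidence of staying.

The Moving-Day threshold is the smallest multiple of a rounding step
(default 1 km) such that at least a target fraction (default 80%) of daily
effective distances fall below it, with the achieved coverage reported.
Rounding reflects how such thresholds are actually used in the field; an
exact empirical quantile would rarely be a round number. The threshold is
fitted pooled across birds and age classes (one movement regime per
population); a day exactly at the threshold counts as Staying — moving
means displacing *strictly* more.

## Residence-area segmentation

Within an analysis window (default 1 October – 31 December, per year, the
period of rapid surface-water change), days are labelled Moving/Staying;
maximal calendar-contiguous runs of ≥ 2 Staying days are candidate Areas.
Each candidate's 95% minimum convex polygon peels the `floor(0.05 n)`
points farthest from the arithmetic-mean centroid (stable sort, so ties
keep input order) and takes the convex hull. Consecutive candidates whose
MCPs intersect are merged — the bird moved but returned to the same place —
with the merged polygon recomputed and compared onward, left-to-right,
repeated until stable.

Open design points, resolved as follows:

* **Projection.** Hulls and intersections are planar operations, so fixes
  are projected with a local equirectangular projection about the window's
  mean coordinate. At ≤ 3,000 km² scales its distortion is negligible
  relative to fix error.
* **Overlap rule.** "Overlap" means non-empty intersection *including* a
  boundary touch; a binary field rule needs a deterministic boundary case.
* **Degenerate polygons.** Fewer than 3 distinct points after peeling give
  a point/segment geometry, flagged, and buffered by one raster cell
  (500 m) for the overlap test only.
* **Dispersion statistics.** Sample (n−1) standard deviations throughout;
  a single-area group reports SD 0 with a degeneracy flag.

## Kernel home ranges

Annual ranges use May→April season-years (so a season never straddles an
age-class boundary) with at least 30 fixes (configurable; fewer fixes give
unstable bandwidths). The bandwidth is the classic reference value
`h = 0.5 (sd_x + sd_y) n^(−1/6)` in metres with sample SDs — the convention
of the standard home-range toolkit, stated explicitly so users can compare
against alternative estimators. The KDE is a bivariate normal kernel with
equal, independent axis bandwidths evaluated at the centres of 500 m cells;
the grid extends 4h beyond the data bounding box (≥ 3h is required for the
95% isopleth to lie inside; 4h makes the truncated mass negligible) and is
renormalised to total mass exactly 1.

Isopleth areas rank cells by density (descending, stable order) and take
the *smallest* cell set whose cumulative mass reaches the level; ties at
the boundary density are included only as far as needed, in scan order.
This follows the "smallest set" definition of a highest-density region and
keeps the uniform-density case exact (half the mass of a uniform grid is
half its cells); including all tied cells would double that area.
Cumulative (all-bird) ranges pool fixes rather than averaging annual
densities: pooling weights each fix equally, which matches how the
cumulative map is read (where the population was), and needs no convention
for unequal tracking durations.

## NDWI composites and phase sampling

NDWI = (Green − NIR)/(Green + NIR), computed cell-wise; a cell with zero
total reflectance is missing, not 0. Composites cover half-open 8-day
windows `[start, start + 8 d)` — bit-exact date assignment — and are usable
only with ≥ 92% good pixels and ≤ 2% unclassified (bounds inclusive).
Sampling is nearest-cell: the index carries per-pixel classification
semantics, and interpolating across a land/water boundary is not
meaningful. The daily mean is fix-weighted (no deduplication of fixes
falling in the same cell): a day spent mostly in one cell *should* weight
that cell.

Each residence area yields four phases: `presence` (one sample per
occupied day from that day's own fixes), `pre_abandonment_week` /
`post_arrival_week` (the presence samples of the last/first 7 occupied
days; all days for shorter stays), and `post_abandonment` — for each of
the 7 days after departure, the full set of occupancy fix locations
re-evaluated on the composite covering that later day. The bird is gone,
so no new fixes exist there; re-evaluating the occupied locations is the
only physically coherent reading of "the locations one week after
abandonment". Each post-abandonment day is assigned to its own covering
composite (no averaging across straddling windows). Days whose composite
is missing or fails QC are skipped and logged.

## Paired binomial mixed models

Model (a) codes presence 0 / post-abandonment 1 with the daily mean NDWI
entered as a degree-2 **orthogonal** polynomial: an abandoned site may have
become either drier or wetter, so the response need not be monotone, and
orthogonal columns (zero mean, unit norm, built by the standard three-term
recurrence so new values can be projected onto the training basis) keep
the two coefficients on comparable scales, unlike raw powers. Model (b)
codes last-week-before-abandonment 0 / first-week-after-arrival 1 with
NDWI linear, pairing each area with its successor; areas without a
successor are dropped. Pairing is restricted to consecutive areas of the
same bird within the same season (the analysis windows are yearly, so
cross-year "successors" cannot arise).

Random intercepts: year, bird, and Area nested within bird, the nesting
enforced by keying area levels as `bird:year:ordinal` so equal ordinals
never pool across birds or years. The season year (May→April) is used for
the year level, which keeps an area's early-January post-abandonment
samples with the area itself. Single-level factors are dropped with a
warning.

Estimation is Laplace-approximated maximum likelihood: for candidate
variance parameters, the joint (β, b) mode is found by penalised Newton
iterations with step-halving (PIRLS; convergence at gradient
< 1e−9·|log-lik|), and the profiled Laplace deviance
`−2[ℓ(y|β̂,b̂) − ||b̂||²/2] + log det(Z'WZ + I)` is minimised over the
log-SDs by Nelder-Mead (xatol 2e−3, fatol 5e−4; log-SDs clamped to
[−6, 5] — below exp(−6) a component is numerically zero and the surface is
flat, which would stall the simplex). The optimiser identity and
tolerances are recorded in every fit report. Fixed-effect uncertainty is
the β block of the inverse penalised Hessian at the optimum (Wald z, as in
the standard mixed-model summary table; no likelihood-ratio machinery).
The fitter was validated against `lme4::glmer` (agreement to < 0.05 on
fixed effects and random-effect SDs on a seeded fixture).

Separation raises a diagnostic error rather than returning a silent
fallback, detected two ways: the fixed-effect linear predictor diverging
past ±100 during Newton iterations, or every observation fitted at class
probability 1 − 1e−6 at the optimum.

R² follows the logit-link variance decomposition: marginal
`σ²_f / (σ²_f + Σσ²_r + π²/3)` with `σ²_f` the sample variance of the
fixed linear predictor; conditional adds `Σσ²_r` to the numerator.
Response curves are population-level (random effects at zero) inverse-logit
predictions with delta-method 95% CIs; grid values outside the observed
NDWI range are flagged as extrapolation.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study system: hourly fixes
06:00–18:00 (+02:00); multi-day stays with geometric durations (mean
14 days — the reported average residence time — truncated at the 2-day
minimum so every stay can legally become an Area); single relocation days
with jumps of 5–20 km (well above the threshold) in uniform random
bearings inside a per-bird wander box; isotropic 300 m Gaussian fix
scatter; a 6-bird, 3-season (Oct–Dec 2013–2015) default design sized to
give roughly 2,000 paired model-a rows per replicate; and 8-day, 500 m
NDWI composites with a dry-land baseline of −0.5 (matching the reported
mean occupied values around −0.5), white spatial noise (SD 0.03), small
year/bird/area random offsets (SD 0.02 each), and a per-area trend δ
applied to the area's 2 km footprint after its scheduled abandonment
(composites straddling the abandonment receive δ scaled by the fraction of
their window after it). Presets anchor δ to the two observed directions —
drying −0.05 and wetting +0.10 — plus a null (δ = 0) for the selection
model. All randomness flows from one seeded generator held in the config;
no global state.

Not emulated: behaviourally realistic movement (correlated random walks,
Ornstein–Uhlenbeck attraction), spatially autocorrelated NDWI fields
(white noise keeps the oracles simple; a smoothing flag exists for realism
checks), rainfall/vegetation covariates, cloud-mask geometry beyond the
composite-level QC fractions, and transmitter failure. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
kind — boundary placement, threshold behaviour, the sign and approximate
size of surface-water shifts, calibration of the null selection model —
not that real tracking archives are free of the additional noise sources
above.

Problem sizes in the test suite and acceptance script (6 birds, 3
seasons, ~2,400 paired rows, 50 replicates for the recovery rates) are the
package's default study conditions; they were chosen to give stable rates
while keeping a full run in minutes on a laptop core.

## Known limitations

* The pipeline consumes generic 2-band or precomputed-NDWI rasters in a
  simple TIFF + JSON-sidecar layout; converting satellite archive formats
  (e.g. MODIS HDF) into it is deliberately outside the package boundary.
* The equirectangular projection is adequate at wetland scales but not for
  continental tracks; no projection library is bundled.
* Wald tests assume the Laplace curvature is trustworthy; with very few
  grouping levels (e.g. 3 years) the year variance is weakly identified,
  which inflates conditional R² more than marginal R².
* The death/transmitter-loss truncation rule ("no movement for several
  days") is exposed only as a config parameter (default off), since no
  defensible universal day-count exists.
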