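# Methods

`sealhab` implements a winter habitat-use analysis for satellite-tracked
female Antarctic fur seals and its overlap with the krill fishery, as a
reusable, fully tested pipeline. Because the original PTT telemetry and the
CCAMLR haul records are not publicly deposited, the package ships a
synthetic study system with known ground truth; every stage is validated
against that truth, against closed-form oracles, or against the published
deployment metadata. This note records the models, the parameter choices
that matter, and what the synthetic validation does and does not show.

## Coordinate conventions

All movement modelling, smoothing and area computation happens in a
spherical Lambert azimuthal equal-area plane centred on 54.01°S, 36.3°W
(just east of South Georgia), in km, with Earth radius 6371 km. Raw records
are lon/lat WGS84; distances on raw records (QC stage, colony distance) are
great-circle. Rasters are regular lon/lat grids, row 0 at the southern
edge, half-open cells (`[edge, edge + d)` in both axes), with exact
spherical per-row cell areas used for every km² figure.

## Telemetry quality control

Cleaning reproduces the standard ARGOS pre-processing chain for winter
(May–September) tracking data:

1. duplicate timestamps resolved by location-class quality (3 > 2 > 1 > 0 >
   A > B), then first occurrence;
2. records outside calendar months 5–9 removed;
3. class-Z (invalid) fixes removed — A/B/0 are retained;
4. a speed–distance–angle filter: interior positions whose implied speed to
   *both* temporal neighbours exceeds 10 m/s are removed; then out-and-back
   spikes — internal vertex angle < 15° with both adjacent steps > 2.5 km,
   or < 25° with both > 5 km — are removed one at a time (sharpest vertex
   first, geometry re-evaluated after each removal) until stable; finally
   track endpoints are dropped if their single neighbour speed exceeds the
   limit. One-at-a-time spike removal is deliberate: two adjacent noisy
   vertices can both violate the wedge test although removing the worse one
   repairs the other, so simultaneous removal over-removes.
5. positions in land cells (depth raster ≥ 0) removed; points off the grid
   are treated as at-sea because there is nothing to test them against;
6. tracks split where the gap between successive uplinks strictly exceeds
   72 h.

Deployment summaries compute whole-day durations (end date − start date)
per animal and per-group mean ± sample (n−1) SD, rounded to integers for
reporting. The published 14-animal deployment table for the 1999/2003 Bird
Island deployments ships with the package and is reconstructed exactly by
this arithmetic (45 ± 28 d, 116 ± 49 d, 76 ± 52 d).

## CTCRW regularization

Each cleaned segment is modelled as an integrated Ornstein–Uhlenbeck
process per axis: velocity `dv = −β v dt + σ dW`, position its integral;
stationary velocity SD is `σ/√(2β)`. Observations are the projected
positions plus isotropic Gaussian error with fixed per-class SDs, default
{3: 0.3, 2: 0.5, 1: 1.0, 0: 3.0, A: 5.0, B: 10.0} km — the order of
published ARGOS error calibrations. These analysis-side SDs deliberately
differ from the synthetic generator's truth; the mild misspecification is
realistic and the recovery tests pass under it.

The likelihood is exact via the Kalman filter over the irregular uplink
gaps; the two axes are independent and share (β, σ). Initial state:
position diffuse (SD 100 km) centred on the first fix, velocity stationary.
Estimation maximises the likelihood over (log β, log σ) with L-BFGS-B from
multiple starts (β ∈ {0.1, 1, 5} h⁻¹; σ initialised from the empirical
displacement scale). Segments with fewer than 10 fixes are passed through
unmodelled and flagged. Prediction runs an RTS smoother over the union of
observation times and a regular 3-hour grid anchored at the segment's first
fix, returning grid positions with per-axis smoothing variances; no
positions are emitted across the >3-day gaps that split segments, so the
model never interpolates over unobserved excursions.

Validation: on segments of ≤5 fixes the filter log-likelihood and smoothed
means agree with a direct joint multivariate-normal construction to better
than 1e-6 relative; β recovery from 500-fix simulated tracks lands in
[0.35, 0.65] for truth 0.5 h⁻¹ across 10 seeds; smoothing reduces RMSE
against the simulated truth below the raw measurement error.

## Habitat dataset

The model domain is the sea area between a northern front polyline and a
southern ice-extent polyline, held as a cell mask with its exact area.
Presences are the 3-hourly smoothed positions inside the domain. For each
presence, three pseudo-absences are drawn uniformly over the domain *area*
(longitude uniform, latitude uniform in sin φ, rejection against the
mask), with no spatial exclusion buffer; each inherits its presence's
calendar month so dynamic covariates and monthly CV blocks are defined for
it. Covariates: containing-cell lookup for raster layers (dynamic layers by
the point's month), great-circle distance to the nearest colony for CDIST
(straight-line, not around-land), chlorophyll on the natural-log scale.
Rows with any missing covariate are dropped and counted.

Collinearity screening is the pairwise variant of the usual VIF procedure:
find the pair with the largest |Pearson r|; if above 0.7, drop the member
with the higher VIF against all remaining covariates; repeat. Exact VIF
ties (duplicated layers) fall back to the higher total correlate, then the
alphabetically later name.

Aspect (compass bearing of the downslope direction, 0° = north-facing) is
fitted as an ordinary smooth of the raw degree value, not as a circular
covariate — the simplest reading of the source analysis; the wrap-around
discontinuity at 0/360° is a known limitation.

## Habitat model

Presence/absence is modelled by a binomial GAM with a logit link: an
intercept plus one penalized smooth per covariate. Smooths are natural
cubic regression splines with k = 4 knots at quantiles of the training
values, penalized by the exact integrated squared second derivative; the
penalty's two-dimensional null space (constant + linear) is raised to 10%
of the smallest positive eigenvalue, so a large smoothing parameter can
shrink a smooth entirely to zero (soft variable selection). Each smooth is
centred (sum-to-zero over training data); evaluation extends linearly
beyond the boundary knots. Fitting is penalized IRLS with step-halving;
smoothing parameters minimise the UBRE/AIC-type criterion
`(deviance + 2·γ·edf)/n` with γ = 1.4, the standard inflation that
counteracts the well-known undersmoothing of the γ = 1 criterion, searched
by a coordinate sweep over log λ followed by Nelder–Mead refinement. The
effective df of each smooth is bounded by k − 1 = 3.

ROC metrics: AUC is the rank (Mann–Whitney) statistic with half-credit
ties; sensitivity and specificity are evaluated at the Youden-optimal
threshold (`threshold=` accepts a fixed probability as an alternative,
since the original choice is not stated and both conventions are in use).

Cross-validation is month-blocked and deliberately *inverse*: for each
month the model trains on that month alone and is scored on all remaining
months, K = number of distinct months; aggregates are unweighted fold
means. This is a conservative scheme for spatio-temporally autocorrelated
telemetry. Forward stepwise selection first ranks all single-covariate
models by aggregate CV AUC (the per-covariate metric table), then
repeatedly adds the candidate with the largest AUC gain, stopping when the
best gain is ≤ 1e-4 (a strict "did not increase" needs a floating-point
tolerance); ties break alphabetically so the path is independent of
candidate order. The final reported/predicting model is refit on all months
pooled. Individual-seal random effects are intentionally omitted (standard
GAMs, not GAMMs); no interaction smooths.

## Prediction and fishery overlap

Prediction assembles per-cell covariates over the domain with CDIST
substituted by distance to the nearest of *all* supplied colonies, uses the
month's dynamic layer (or the May–September mean for pooled surfaces), and
leaves cells with any missing covariate blank; blank cells never count
toward areas. Threshold masks keep cells with probability strictly above
0.50 / 0.95; mask area is the sum of spherical cell areas.

Fishery overlap assigns hauls to grid cells by start position (continuous
trawls are represented by haul starts only). The fishery footprint is the
area of mask cells containing ≥ 1 haul — a cell-based definition, declared
rather than inferred, whose value scales with the grid resolution reported
alongside every summary. Catch-within sums the catch of hauls in mask
cells; percentages are taken against the mask area and against a reference
total catch. Hauls outside the grid count toward total catch only. The
catch kernel density is a catch-weighted isotropic Gaussian KDE on the
projected plane (default bandwidth 25 km) whose integral over the grid
equals the total catch up to boundary truncation.

## Synthetic study system

The generator emulates the study inputs at scaled-down size:

- **Terrain**: a smooth random seabed (mean −3200 m) with an island cone
  (land ≥ 0, radius 40 km), an east–west elongated shelf, two offshore
  rises (NW and SE of the island) and a trough south of the island. The
  rises/trough matter: they keep depth from being a deterministic function
  of colony distance (domain-wide r ≈ −0.45), as in the real region where
  offshore rises are shallow yet far from any colony. Shallow banks
  saturate smoothly toward −15 m so no sea cell has an exactly zero
  gradient (aspect stays defined). Slope/aspect/slope-SD are derived by
  central differences on the metre scale.
- **Dynamic fields** (SST, log-chlorophyll, wind-stress curl): fixed
  spatial base + seasonal trend + slowly rotating anomaly, so monthly
  layers vary smoothly month to month — independent monthly fields would
  make month-blocked CV trivially pessimistic.
- **Movement**: biased correlated random walk in the projected plane;
  16 candidate headings per 3-h step, gamma step lengths (mean 10 km),
  softmax over directional persistence (κ = 3) plus the planted preference
  applied to covariates standardized over sea cells. Land and off-grid
  candidates are inadmissible. Persistence 3 makes full out-and-back
  reversals on >5 km steps rare, as for real transiting seals; the default
  planted preference {CDIST: −3, DEPTH: +2.5} (log-odds per domain SD)
  concentrates seals within a few hundred km of the colony, mirroring the
  described coastal winter distribution.
- **ARGOS corruption**: exponential inter-uplink gaps with mean 6 h
  (matching the ~4 locations/day implied by the published deployment
  table), class mix {3: .10, 2: .15, 1: .20, 0: .15, A: .20, B: .15,
  Z: .05}, per-axis class SDs {0.25, 0.5, 1.0, 2.0, 2.5, 5.0} km anchored
  to published calibrations, and a configurable fraction of interior fixes
  displaced far enough that the implied speed to both neighbours exceeds
  10 m/s. Records carry `is_spike`/`is_Z` provenance flags for tests.
- **Fishery**: haul starts in shelf-break depth-band cells (optionally
  further masked), season-uniform dates, log-normal catches.

What the synthetic system does *not* emulate: real oceanographic structure
or fronts, tides and advection, behavioural modes (resting vs transiting),
haul-out periods, tag duty cycling, or multi-year environmental change.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under realistic noise — not that the ecological conclusions for
the real system are reproduced, which would require the restricted
telemetry and catch data.

## Problem sizes and determinism

Simulation studies use sizes chosen to characterise behaviour crisply:
10-seed fleets of 3 seals × 60 days for filter validation; 500-fix
segments × 10 seeds for CTCRW recovery; 10 replicates of 6 seals × 150
days (May–September, matching the 6–8 animals per modelled period in the
published deployment table) for selection recovery. Every random draw
flows from an explicit integer seed through `numpy.random.default_rng`;
identical seeds give byte-identical outputs. `scripts/acceptance.py
--seed N --out file.json` re-runs the whole battery from one seed.

## Known limitations

- The smoothing-parameter criterion is prediction-error based, not REML;
  for very small folds λ estimates are noisy (mitigated by shrinkage).
- Sensitivity/specificity depend on the threshold convention; Youden is
  the default and a fixed threshold is available, but the two are not
  comparable across datasets with different prevalence.
- CDIST is straight-line distance and can cross land.
- The footprint definition is resolution-dependent by construction.
- With geographically correlated drivers (colony distance and depth), a
  single realization can contain almost no independent signal for the
  weaker driver; selection then legitimately returns the parsimonious
  model. The acceptance study tolerates up to two such seeds in ten.
- At the default 3:1 pseudo-absence ratio and planted signal strength,
  fitted probabilities top out around 0.9, so the >0.95 core-habitat mask
  can be empty on synthetic fleets; the >0.50 mask carries the overlap
  signal. A sharper planted preference would populate the upper mask but
  make the selection problem trivial.
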