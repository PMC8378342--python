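# Methods

## Scope and data model

`esdm` models habitat suitability from presence-only occurrence records and a
stack of gridded environmental predictors, then projects range change under
additive climate-shift scenarios. Grids are regular geographic lattices
(EPSG:4326) with cell centers at `min + (i + 0.5)·cell_size`, half-open cell
intervals, rows running north→south. The default study window is the
Indo-West Pacific, 50°E–180°E and 50°S–50°N, at 5-arc-minute resolution;
longitudes in [−180°, 360°) are accepted and normalized to [−180°, 180°).
The six canonical predictors are mean temperature `T` (°C), salinity `Sal`
(PSS), current velocity `CV` (m/s), ice thickness `Ice` (m), ocean depth
`Depth` (m), and distance to shore `Dshore` (km). Land/nodata cells carry
NaN; every statistic is computed over the jointly valid (sea) cells of the
stack. GeoTIFF I/O is implemented on tifffile with the standard
georeferencing tags (pixel scale, tiepoint, WGS84 geokeys, GDAL nodata).

## Predictor screening

Collinearity is screened with the pairwise Pearson correlation over the
jointly valid cells (optionally a seeded random subsample). Selection is a
greedy scan in a user-supplied priority order: a layer is retained iff
|r| < 0.7 against every layer already retained. The threshold is interpreted
on the absolute value — the standard collinearity convention — and a layer
with undefined correlation (a constant layer) is treated as violating the
threshold, so it survives only if it heads the priority list. The retained
set therefore never contains a pair with |r| ≥ 0.7, but it does depend on
the priority order; with real data the order should encode ecological
preference, and the default keeps the six canonical predictors first.

## Occurrences and pseudo-absences

Records are thinned to at most one per grid cell (first record in input
order wins) before extent filtering; both counts are logged. Because true
absences are unavailable, `n = 5000` pseudo-absence points are drawn,
seeded and uniformly, from sea cells in *contrasting environmental
conditions*: cells whose predictor vector falls outside the presence surface
range envelope at the 2.5/97.5 percentile bounds. Points sit at cell
centers, never in a presence cell; if fewer eligible cells exist than
requested, sampling is with replacement (logged), and a pure-random
background strategy is selectable in the config. The 0.025 envelope
quantile is a convention, not an estimate, and is exposed as a parameter.

Presences and pseudo-absences get class-balanced case weights (each class
sums to half the total weight), so an 82-vs-5000 design is not degenerate:
fitting sees prevalence 0.5 regardless of the imbalance.

## The learner zoo

Ten algorithms sit behind one contract: `fit(spec, table, rows) →` a model
whose predictions on any input lie in [0, 1] and are deterministic given
(spec, data, seed). One master seed fans out deterministically (via
`numpy.random.SeedSequence`) to pseudo-absence sampling, fold splitting, and
every stochastic learner.

| id | implementation | notable defaults |
|---|---|---|
| GLM | unpenalized logistic regression | — |
| GAM | cubic-spline basis per predictor + ridge-stabilized logistic | 5 knots |
| CTA | single classification tree | min split 20, min leaf 7 |
| GBM | gradient-boosted trees | 2500 trees, depth 3, shrinkage 0.01 |
| ANN | single-hidden-layer perceptron | size 8; optional internal 3-fold CV over {2,4,6,8} when size is unset |
| SRE | surface range envelope, first principles | quantile 0.025 |
| FDA | shrinkage-regularized linear discriminant on a piecewise-linear spline basis, equal class priors | 5 knots |
| MARS | first-order adaptive (piecewise-linear) spline basis + logistic | 10 quantile knots |
| RF | random forest | 500 trees |
| MAXENT | L2-penalized logistic on linear+quadratic features, presences vs. background | C = 1 |

All defaults live in one config block (`ALGORITHM_DEFAULTS`), are overridable
per run, and are recorded on the fitted model. The intent is behavioral
parity with the familiar modelling-framework defaults, not numeric
replication of any external engine — FDA in particular uses a shrinkage LDA
(rather than an unregularized one) because the spline basis makes the
pooled covariance ill-conditioned, and MAXENT is formulated as the
penalized presence/background logistic that is its well-known equivalent,
keeping the package self-contained.

The SRE is implemented from first principles: per-predictor bounds are the
empirical [q, 1−q] quantiles (linear-interpolation definition) of the
presence rows, and a query is suitable (1) iff every predictor lies within
its bounds, inclusive. Each margin therefore keeps ≥ 95% of the presences
at q = 0.025, and joint presence coverage is bounded below by 1 − 6q·2 = 70%
for six predictors; empirically it is ≈ 84% on the default virtual species.
At q = 0 the envelope is the min/max box and is invariant under strictly
monotone per-predictor transforms.

## Evaluation, gating, ensembling

Cross-validation is stratified k-fold (k = 5) repeated 10 times: each
repetition partitions all rows into class-stratified folds, so every fit
trains on (k−1)/k = 80% and is scored on the held-out 20%. Held-out scoring
is unweighted: AUC is the rank-based (Mann–Whitney) statistic with ties
counted half — identical to the trapezoidal area under the empirical ROC —
and TSS is evaluated at the TSS-maximizing threshold, searched over the
midpoints between consecutive distinct scores plus {0, 1}, ties broken
toward the smallest threshold. The predicted-positive convention is
score ≥ threshold; it matters only for exact-tie cells.

Per-algorithm means over repetitions × folds pass the strict retention gate
(mean TSS > 0.80 **and** mean AUC > 0.85). Retained algorithms are refitted
once on the full table and combined as a weighted average with weights
proportional to the CV mean of the gating metric (TSS by default, AUC
selectable) — one member per algorithm. The ensemble is convex, so its
predictions lie within the envelope of member predictions. The binarization
threshold is the TSS-maximizing threshold of the ensemble scores on the
training table; it is frozen from the current period and reused for every
future scenario.

Whether the gates should apply to CV means or to full-data refits is an
open protocol question; CV means are used here because the refit has no
held-out data to score.

## Importance and response curves

Variable importance of predictor *j* is `1 − Pearson(p, p_j)` where `p` are
reference predictions on the training table and `p_j` predictions after
shuffling column *j* (seeded), averaged over 10 permutation runs with the
standard error over runs. Values are reported unclamped (1 − r > 1 when the
shuffled predictions anticorrelate); constant predictions define importance
0. Response curves are evaluation strips: one predictor sweeps 100 evenly
spaced points across its training range while the others are fixed at
training means (medians selectable).

## Scenarios and range change

A scenario is a set of additive shifts on the dynamic layers (T, Sal, CV,
Ice), uniform or spatially varying; depth and distance to shore are constant
by assumption, enforced as identically zero shifts. The eight built-in
scenarios are the RCP2.6/4.5/6.0/8.5 mean shifts for the 2050s and 2100s
(e.g. T +1.10 °C for RCP8.5/2050s, +2.87 °C and Sal −0.26 for
RCP8.5/2100s).

Range change compares the current and future binary maps on a shared grid
and mask: lost = suitable→unsuitable, gained = unsuitable→suitable, stable =
suitable in both, all expressed as percentages of the *current* suitable
range, so `PercLoss + PercStable = 100` and
`SpeciesRangeChange = PercGain − PercLoss = 100·(future − current)/current`
hold as identities. Ranges are valid-cell counts — the identities then hold
exactly — with a cos(latitude) area-weighted variant available but off by
default; using the current range as the gain denominator is the only reading
under which the net-change identity holds column-wise.

## The virtual-species generator

The generator exists so every stage is testable offline. It emulates:

* **Fields.** Seeded Gaussian noise smoothed to a stated correlation length
  (default 6 cells; 0 gives uncorrelated cells), standardized over sea cells
  to the current-period means/spreads (T 22.72 ± 4 °C with a latitudinal
  gradient, Sal 34.51 ± 1.2, CV 0.10 ± 0.08 clipped at 0). Ice is zero
  except poleward of ±45°, where a small non-negative ramp applies.
* **Geometry.** A synthetic coastline from an independent smooth field
  (default 30% land). Depth and distance to shore derive from the normalized
  distance-to-coast, so their value ranges (up to ~6000 m and 1000 km) do
  not depend on grid resolution.
* **Niche.** Suitability is a weighted product `Π r_i(x_i)^{w_i}` of
  per-predictor responses (gaussian, logistic, or flat). The default species
  is coastal and shallow-water: logistic declines at 200 km from shore and
  400 m depth (steep: widths 20 km and 50 m, giving a crisp range boundary),
  a gaussian thermal optimum at 22.0 °C (width 5) — deliberately below the
  current mean so warming shrinks the true range — moderate salinity and
  weak current responses, no ice effect. Relative weights (Dshore 0.47,
  Depth 0.44, T 0.23, Sal 0.14, CV 0.08, Ice 0) give the depth/shore-
  dominated importance structure the package targets.
* **Sampling.** Presence-only: each sea cell gets one Bernoulli draw with
  p = suitability^γ (γ = 1 by default) and accepted cells, in seeded random
  order and without replacement, become presences until the target count
  (default 82) is reached; an unreachable target raises with the achieved
  count. The ground truth keeps the per-cell suitability and a binary map at
  a fixed 0.5 truth threshold — the pipeline's threshold is learned, never
  copied.

What the generator does **not** emulate: AOGCM spatial structure in the
future deltas (shifts are means, optionally user-supplied fields), ocean
currents and dispersal, sampling bias in the presence records, and
observation error. Passing recovery tests therefore demonstrate internal
consistency of the pipeline — that it can recover a known niche, ranking,
and range boundary under clean sampling — not performance on biased
real-world occurrence data.

## Problem sizes and numerical choices

The test suite validates the full protocol on a 6400-cell (80×80) grid with
300 presences, 5000 pseudo-absences, all ten algorithms, and 5-fold × 2-
repetition cross-validation; unit tests use a 20×20 window and fast
hyperparameter overrides (the behavior under test is the contract, not the
default capacity). At those sizes the recovered ensemble binary map reaches
TSS ≈ 0.89 against the ground truth and the two niche-dominant predictors
rank top-2 in permutation importance in 10/10 replicate seeds; the envelope
model is the weakest member by AUC, and with small samples it is the typical
gate failure, mirroring experience with real data.

Numerical conventions worth knowing: quantiles use linear interpolation;
threshold ties break toward the smallest maximizer with a 1e-12 strict-
improvement guard; ensemble weights must sum to 1 within 1e-9; suitability
maps tolerate 1e-9 of float slack at the [0, 1] boundary; binarization uses
≥; degenerate fits (single-class subsets, all-constant predictors) raise a
`FitError` carrying the algorithm name; a constant layer's correlations are
reported as NaN, never 0.

## Known limitations

* Percentages are cell counts, not geodesic areas, by default.
* Full dispersal is implicit: a cell that becomes climatically suitable is
  counted as gained regardless of reachability.
* The greedy collinearity filter is order-dependent by design.
* The per-fold model store is transient; only the full-data ensemble
  members are serialized.
* No extrapolation-risk (MESS-style) diagnostics: projections under large
  shifts can query learners outside their training envelope, where tree
  ensembles saturate and splines extrapolate linearly.
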