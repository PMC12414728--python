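# Methods

## Model

The data are `n` time-stamped planar locations `S = (t_i, s1(t_i), s2(t_i))`
of one animal, in meters, with arbitrary (irregular, possibly tied) record
times. The model makes no distributional assumptions about movement or
residuals: it bags a local regressor of location on time.

For each of `B` bootstrap resamples of the rows, a k-nearest-neighbor
regressor is fit per coordinate. Because the feature (time) is
one-dimensional, the k nearest neighbors of a query always form a
contiguous window in time order, and predictions are computed by a
vectorized sliding-window search rather than a generic neighbor index.
Tie-breaking is fully specified so runs are byte-reproducible: distance
ties go to the earlier time, then the lower row index; the unit tests pin
this to a brute-force reference on tie-rich instances. The weighted variant
uses inverse-distance weights over the k neighbors, with exact
interpolation (unweighted mean of zero-distance neighbors) at observed
times.

Aggregation over the ensemble gives:

* the **bagged expected path** — the pointwise member mean on a time grid;
* an **out-of-bag residual pool** — for each record left out of at least
  one resample, the residual between the observation and the mean
  prediction of the members that left it out (aggregation first, then one
  residual per row, keeping the pool size interpretable and the
  (coord1, coord2) pairing intact);
* **location prediction intervals** — the expected path shifted by
  empirical OOB-residual quantiles (per coordinate, rectangular regions;
  joint elliptical regions are out of scope). Residual quantiles are
  clipped to bracket zero so the bounds always contain the center path;
* **path realizations** — either the member paths themselves, or the
  expected path plus residual pairs resampled from the OOB pool at each
  grid time.

## Derived quantities

Scalar summaries of a path: net displacement between two instants (not path
length — the two definitions differ, and only net displacement is
consistent with a single straight relocation), the per-interval
displacements and their average, the minimum distance to point/segment
features, and the proportion of grid time within radius `r` of any feature
(a Riemann fraction on a uniform grid; the error vanishes as the grid step
shrinks). Time queries snap to the nearest grid point within half the grid
spacing. The point estimate of a derived quantity is the functional of the
bagged mean path; the interval is the empirical percentile range of the
functional across the B member paths (an ensemble-median point estimate is
available as a switch).

For an *averaged* quantity such as the mean per-minute displacement, the
evaluation harness additionally summarizes coverage component-wise: one
percentile interval per minute, coverage averaged over minutes. This is the
reading used for the drifting-circles study table.

The evaluation harness exposes three interval constructions for derived
quantities (`ci_mode`): `ensemble` (percentiles across member paths; the
default), `oob_perturbed` (percentiles across OOB-residual-perturbed copies
of the mean path), and `predictive` (member paths plus residual noise —
both uncertainty sources). See "Known limitations" for why this switch
exists.

## Bootstrap schemes

`iid` resamples rows uniformly with replacement. `blocked` partitions the
(time-sorted) rows into contiguous blocks of near-equal size on record
ranks — irregular sampling therefore cannot create empty blocks — and
resamples with replacement within each block, preserving per-block counts
exactly. The default block count targets ~20 records per block: large
enough to retain local KNN structure inside a block, small enough to
respect serial dependence. Out-of-bag status is computed over the full
index set in both schemes. Moving-block, stationary and tapered bootstraps,
and automatic block-length selection, are out of scope.

`k` can be chosen by out-of-bag error: for each candidate, a small ensemble
(the same bootstrap samples for every candidate, for a paired comparison)
is fit and the pooled OOB RMSE over both coordinates is minimized, ties to
the smallest k. The default when selection is not invoked is k = 5.

## Synthetic data

Two true-path generators define the study conditions; both are expressed in
meters and produce a dense uniform grid with iid Normal path noise (sd 1 m
per coordinate per grid time) as the stochastic, non-location-error
component of movement.

**Abrupt stepwise** (15 days, 1-min grid): stationary at (0, 0) until
minute 10,600, linear transit to (4000, 4000) completed at minute 11,000,
stationary after — a dispersal burst of ~5657 m net on the eighth day. The
roadway layout is three 6-km segments perpendicular to the transit
diagonal, crossing it between the sites (lines x + y = 2000, 4000, 6000);
the true proportion of time within 200 m of a road is ~0.004.

**Drifting circles** (25 min, 1-s grid): `z1 = r(t)·sin(φt) + t`,
`z2 = r(t)·cos(φt) + t`, with radius ramp `r(t) = αt + β` up to the
midpoint and `γ − αt` after (`γ = 1500α + β` forces continuity). Defaults:
φ = 2π/19.65 rad/s, α = 0.36 m/s, β = 30 m (peak radius 300 m), drift 1 m/s
per coordinate. The rotation period (~20 s) is deliberately faster than the
telemetry sampling can resolve at the study sample sizes — the model then
sees the circling as unstructured spread around the drift line, which is
what produces the characteristic positive bias of displacement estimates in
this design. The turbine layout is a 3×3 point grid aligned with the drift
diagonal at 1140-m spacing, centered on it; the true proportion of time
within 100 m of a turbine is ~0.037. These constants are **reconstructions**
calibrated against the true derived-quantity values the study design
implies (true mean minutely displacement ≈ 96 m; small p-proportions);
different choices change the absolute study numbers but not the pipeline.

**Location error**: one family per record, equal thirds Normal(0, σ),
Uniform(−ξ, ξ), symmetric Triangular(−η, 0, η); the two coordinates get
independent magnitudes from the shared family. Presets: high
(σ, ξ, η) = (100, 120, 150) m and low (10, 12, 15) m, which put recorded
locations within 300 m / 30 m of the truth about 99% of the time
(Triangular sd is η/√6 ≈ 61 m at the high preset).

Telemetry sampling draws n distinct grid times uniformly without
replacement. What the generator does **not** emulate: fix-rate schedules
and duty cycles, missing fixes correlated with habitat, autocorrelated or
state-dependent location error, behavioral switching beyond the two fixed
patterns. Tests passing on these generators therefore demonstrate
correctness of the pipeline and its frequentist calibration under the
stated designs, not performance on any particular real tag.

## Evaluation harness

A scenario fixes one true path from its seed (shared by all replicates, so
every quantity has a constant truth), then for each of R replicates:
sample telemetry, select k (if a grid is given), fit, and record each
quantity's point estimate and interval. Reported per quantity: truth,
expected estimate, absolute bias, and CP — the exact fraction of replicates
whose interval contains the truth (component-averaged for per-minute
quantities). Replicates draw from independent streams spawned
deterministically from the scenario seed: results are independent of
execution order, and extending R leaves earlier replicates unchanged.
Replicate failures are counted and excluded (zero in nominal runs). For the
abrupt design the harness also reports the closed-form probability
`(1 − 400/21600)^n` that a dataset contains no record inside the
400-minute dispersal window, together with the observed fraction — the
structural driver of the coverage drop at n = 100.

Scenario grids bundled as package data: `abrupt_table1.json` (high/low
error × n ∈ {300, 100}; plain KNN, k by OOB selection over {3, 5, 9, 15},
B = 100, blocked bootstrap, ensemble intervals; quantities d8 and p200) and
`circles_table2.json` (high/low × n ∈ {150, 30}; weighted KNN with fixed
k = 3 — OOB selection is deliberately not used here, because under the
aliased rotation it always selects the heaviest smoothing, which flips the
sign of the displacement bias this design is meant to exhibit; quantities
d-bar and p100).

At these settings the four abrupt scenarios reproduce the design's
signature behavior: essentially unbiased day-8 displacement at n = 300
(|bias| a few meters out of 5657), a ~250–450 m negative bias and a
coverage drop to ~0.86 at n = 100, and near-nominal coverage at n = 300.

## Numerical choices

* Quantiles everywhere are `numpy.quantile` with linear interpolation.
* Grids built from telemetry run first record → last record (the last time
  is always included) and never extrapolate; evaluation at scenario-defined
  times slightly outside a replicate's record range is permitted via an
  explicit `allow_extrapolation` flag (KNN prediction is constant beyond
  the data range, so this is well defined).
* Derived-quantity evaluation on an ensemble is vectorized: member
  predictions are computed once on the union of quantity grids and sliced
  per quantity; path-distance computations are batched across all members.
* Proportion-of-time requires a uniform grid (tolerance 0.1%); a
  non-uniform grid is an error instructing resampling, not a silent
  approximation.
* Degenerate inputs: a single-record telemetry cannot produce an OOB pool
  (B = 1 full-coverage ensembles raise with advice to increase B);
  zero-length segments degrade to points; k > n, empty k-grids, invalid
  levels and nonpositive grid steps all raise with the offending value.

## Known limitations

* The interval construction for derived quantities is the genuinely open
  design choice. The ensemble-percentile default matches the n = 100 rows
  of the abrupt study design closely but is mildly anti-conservative at
  n = 300 (CP ~0.93 where near-nominal-to-conservative coverage is the
  design's signature); the `predictive` construction (member paths + OOB
  residual noise) is conservative at n = 300 but over-covers at n = 100.
  No single construction is simultaneously near-nominal in all four cells
  under the reconstructed constants; both are exposed so the sensitivity is
  one config key away.
* Per-coordinate rectangular prediction regions only.
* The drifting-circles constants are calibrated reconstructions (see
  above); the absolute circles-study numbers depend on them.
* Resource-selection inference, additional learners (trees, SVR) and
  meta-learning over learners are out of scope; the learner interface is
  the extension seam.
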