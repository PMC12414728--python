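# bagmove

Bagged machine-learning animal movement models for telemetry data.

`bagmove` estimates a continuous movement path from time-stamped animal
locations (GPS or VHF telemetry) by **bagging** (bootstrap-aggregating) a
simple regressor — k-nearest-neighbor regression of each coordinate on time
— and turns the ensemble into statistical inference: prediction intervals
for the animal's location at any time, and confidence intervals for
**derived quantities** such as daily net displacement or the proportion of
time spent within a radius of roads or wind turbines. It is aimed at
ecologists and engineers who want frequentist inference from telemetry data
without specifying a mechanistic state-space or hierarchical movement model.

## The model

Telemetry is a matrix `S = (t_i, s1(t_i), s2(t_i))`, `i = 1..n`, of
irregularly timed planar locations (meters). For `b = 1..B`:

1. draw a bootstrap resample `S_b` of the rows — either iid with
   replacement, or stratified within contiguous time blocks to respect
   serial dependence;
2. fit a KNN regressor (plain or inverse-distance-weighted) of each
   coordinate on time to `S_b`, giving a member path `ŝ_b(t)`;

and aggregate on a fine time grid:

* **expected path** — `ŝ_bag(t) = mean_b ŝ_b(t)`;
* **prediction intervals** — each record left out of some resamples gets an
  honest out-of-bag (OOB) prediction; the pooled OOB residuals give
  empirical quantiles that are attached to the expected path;
* **derived quantities** — a functional `θ(path)` (net displacement between
  two times, average per-interval displacement, proportion of grid time
  within radius `r` of point/segment features) is evaluated on the bagged
  mean path (point estimate) and on every member path (percentile
  confidence interval).

A simulation harness replicates whole studies: it fixes a true path `z(t)`
(abrupt stepwise dispersal, or drifting circles with a ramping radius),
samples telemetry with a heterogeneous location-error mixture (equal thirds
Normal/Uniform/Triangular per record), and reports expected estimate,
absolute bias, and coverage probability (CP) of the 95% intervals over
hundreds of replicated datasets.

## Worked example

```python
import numpy as np
import bagmove as bm

rng = np.random.default_rng(1)

# a 15-day dispersal path observed 300 times with heavy location error
truth = bm.abrupt_path(bm.AbruptPathConfig(), rng)          # 1-min grid, meters
tel   = bm.sample_telemetry(truth, 300, bm.ErrorModel.preset("high"), rng)

k     = bm.select_k(tel, [3, 5, 9, 15], rng=rng, scheme="blocked")
model = bm.fit(tel, bm.LearnerSpec("knn", k), B=100, scheme="blocked", rng=rng)

d8 = bm.derived_interval(
    model,
    bm.displacement_quantity("d8", 7 * 1440, 8 * 1440),     # day-8 boundaries, minutes
    level=0.95,
    allow_extrapolation=True,
)
true_d8 = bm.true_derived(truth, bm.displacement_quantity("d8", 7 * 1440, 8 * 1440))
print(f"selected k = {k}")
print(f"true day-8 displacement  = {true_d8:.1f} m")
print(f"estimated                = {d8.estimate:.1f} m "
      f"(95% CI {d8.lower:.1f} - {d8.upper:.1f})")
```

Output:

```
selected k = 5
true day-8 displacement  = 5655.6 m
estimated                = 5619.3 m (95% CI 5515.2 - 5748.2)
```

The animal sat still for ~7 days, crossed ~5.7 km in a 400-minute burst on
day 8, and sat still again; despite per-record location errors of up to
±300 m, the interval for the day-8 net displacement brackets the truth.

The same pipeline is available from the shell:

```bash
bagmove simulate --scenario abrupt --n 300 --error high --seed 1 --out tel.csv
bagmove fit tel.csv --k-grid 3 5 9 15 --B 100 --scheme blocked --seed 1 \
        --grid-step 30 --out path.csv      # path + interval columns
bagmove derive tel.csv --quantity displacement --boundaries 10080 11520 \
        --k 5 --seed 1
bagmove evaluate --scenario-name abrupt_table1 --R 50 --style table1
```

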