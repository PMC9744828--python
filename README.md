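# sleepcourse

A tested, reusable pipeline for analysing self-reported sleep duration
across the adult life-course, together with a spatial-navigation
performance metric derived from game trajectories:

* **`sleepcourse.changepoint`** — exact penalized piecewise-linear
  segmentation of a 1-D signal (per-age mean sleep curve). The objective
  is the summed per-segment least-squares residual plus a fixed penalty
  `beta` per change point, minimized globally by dynamic programming
  (optimal partitioning), with an exhaustive brute-force oracle and a
  threshold sweep for penalty-stability analysis.
* **`sleepcourse.navigation`** — trajectory path lengths, tutorial-sum
  normalization, first-principal-component composites, and the z-scored
  training (TP) and wayfinding (WF) performance scores (mean 0, SD 1,
  higher = better).
* **`sleepcourse.pipeline`** — inclusion filtering (age ceiling, 5–10 h
  sleep range, minimum per-country n), 3-year-window age curves, Hedge's
  g effect sizes, a maximum-likelihood mixed model of sleep on
  demographics with per-country conditional modes, and age-group-specific
  quadratic sleep-vs-performance models with delta-method peak CIs.
* **`sleepcourse.geo`** — cluster ANOVA F with a country-label
  permutation null, latitude/GDP country-level regressions, per-subgroup
  change points, and a packaged 7-cluster / 11-cluster country taxonomy
  (plain CSV; `England` denotes the United Kingdom).
* **`sleepcourse.synthetic`** — a cohort + trajectory generator with
  stored ground truth (three-phase age trend with change points at 33 and
  53 y, gender offset, country random intercepts, integer-hour reporting,
  latent navigation/motor skills with an inverted-U sleep link peaking at
  7 h in the oldest age group), so every stage is testable end to end
  without external data.

## CLI

```bash
# synthesize a cohort (+ ground truth JSON) and trajectories
sleepcourse simulate --n 200000 --seed 1 --out cohort.csv --trajectories trajs.csv

# segment a position,value curve with a penalty sweep
sleepcourse changepoint --input curve.csv --beta 0.02 --sweep 0.005:0.09:0.001

# score TP/WF from trajectories
sleepcourse score --trajectories trajs.csv --out scores.csv

# filter + per-age curve + change points + age-group sizes
sleepcourse agecurve --cohort cohort.csv --min-country-n 500

# cluster ANOVA with a 100-shuffle permutation null
sleepcourse geocluster --cohort cohort.csv --countries countries.csv --shuffles 100 --seed 7
```

Change points are reported as the first position of the later segment
(a change point at 33 separates the segment ending at 32 from the one
starting at 33).

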