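# ssiweight

A pipeline for studying **self-selected interval (SSI) judgments** against
conventional point judgments, in a weight-estimation task subject to the
**size-weight illusion (SWI)** — the robust percept that the smaller of two
equal-weight objects feels heavier.

It is written for judgment/decision and psychophysics researchers who want
to run, simulate, or re-analyze the interval-bisection elicitation
protocol: a respondent states a range `[lower, upper]` of reasonable
weights for a lifted box, then answers three binary probes ("lighter or
heavier than *m*?", where *m* is the integer-rounded midpoint of the
current interval). Each answer keeps one half, so the final interval is
1/8 of the initial width and its exact midpoint (`mid4`) is the
respondent's inferred best estimate.

The package provides:

* **`ssiweight.design`** — the 15-box stimulus set (3 sizes × 5 weights,
  four weights shared between adjacent sizes), session structure, and the
  same-weight adjacent-size comparison pairs: 8 per session, 24 per
  participant, 744 over a 31-respondent cohort.
* **`ssiweight.engine`** — the splitting procedure itself, with
  round-half-even integer probes and exact midpoints.
* **`ssiweight.simulate`** — synthetic observers: a perceptual model with
  multiplicative log-normal noise and a size-dependent heaviness bias, and
  a random-responder null model for chance baselines.
* **`ssiweight.illusion` / `accuracy` / `consistency`** — the metric
  suites: SWI-case counts, interval non-overlap, the SWI-factor
  `(j_small − j_large) / min(j_small, j_large)` with outlier filtering;
  proportional absolute deviation `pad = |j/w − 1|`, strict interval hit
  rates per split, inclusive point-coverage, width regressions and
  correlations; and the relative-SD consistency measure with paired
  comparisons.
* **`ssiweight.cli`** — `simulate`, `analyze`, `elicit` and `reproduce`
  subcommands over CSV trial tables.

See `docs/methods.md` for the model, its assumptions, and every numerical
convention (rounding, quartiles, tie-breaks, aggregation order).

## Worked example

Run the elicitation protocol with scripted answers (heavier, lighter,
heavier) from the initial interval [100, 200] g:

```sh
$ ssiweight elicit --lower 100 --upper 200 --answers h,l,h
interval 1: [100, 200]
interval 2: [150, 200]
interval 3: [150, 175]
interval 4: [162, 175]
best estimate (final midpoint): 168.5 g
```

The probes were 150, 175 and 162 (the midpoint 162.5 rounds to the nearest
even integer); the final midpoint 168.5 is exact and unrounded.

Simulate a full synthetic study and produce every report table:

```sh
$ ssiweight reproduce --seed 7 -o out/
report bundle in out/ (18 files)
```

`out/summary.md` then reports, for this seed:

```
Mean SWI-cases per participant (max 24): point 19.94, mid1 20.13, mid4 21.74
Mean proportional absolute deviation (pad): mid1 37.5%, ... point 35.7%
Interval hit rate per split (pooled): split 1 46.6%, split 2 26.1%, split 3 15.0%, split 4 7.2%
Mean relative SD: point 0.225, mid1 0.226, mid4 0.168
```

Reading: the synthetic cohort shows a strong illusion (≈20 of 24
comparisons judge the smaller box heavier, against a chance expectation of
12), hit rates roughly halve with each interval split, and final interval
midpoints (`mid4`) are more stable across sessions than point judgments —
the qualitative pattern the elicitation method is designed to probe. The
underlying per-trial tables (`trials.csv`, `swi_factors.csv`,
`accuracy.csv`, `consistency.csv`, …) are tidy CSVs ready for external
model fitting.

A random-responder null run is one flag away:

```sh
ssiweight reproduce --seed 7 --mode random -o out-null/
```

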