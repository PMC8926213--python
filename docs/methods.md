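# Methods

## The judgment task and the two elicitation methods

The package models a weight-judgment experiment in which respondents
estimate, in grams, the weight of 15 cardboard boxes that come in three
sizes (small / medium / large, five weights each). Because equal-weight
boxes of different size are judged, every judgment is subject to the
size-weight illusion (SWI): the smaller of two objects of the same weight
is perceived as heavier.

Two elicitation methods are compared:

* **Point judgments** — a single number per box.
* **Self-selected intervals (SSI)** — the respondent first states a lower
  and upper bound covering all weights they find reasonable, then answers
  three binary probes. Each probe is the arithmetic midpoint of the current
  interval, rounded to a whole gram; answering "heavier" keeps the upper
  half, "lighter" the lower half. After three splits the final interval is
  one eighth of the initial width (exactly, when probes are not rounded),
  and its exact midpoint (`mid4`) is taken as the respondent's best
  estimate. The initial interval's midpoint is `mid1`.

### Probe rounding

The elicitation computer rounds each probe to a whole gram using
round-half-to-even; with integer bounds only the x.5 case invokes the tie
rule, and both half-even and half-down reproduce the canonical
162.5 → 162 example ([150, 175] → probe 162). Half-down is available as a
configuration switch (`rounding="half-down"`). Recorded interval endpoints
use the rounded probe; stored midpoints `mid1..mid4` are exact means and
the final best estimate is never rounded.

One degenerate case needs a rule the protocol itself does not supply: an
interval of width ≤ 1 g contains no integer strictly between its bounds, so
a rounded probe would coincide with an endpoint and the split would be
undefined. In that case the engine probes with the exact (unrounded)
midpoint, which keeps the procedure total on arbitrarily narrow intervals.
Consequently the width-contraction law "child width ∈ {⌊w/2⌋, ⌈w/2⌉}" holds
for parents of width ≥ 2; narrower parents halve exactly.

## The stimulus design

The default design (`build_default_design`, also shipped as
`data/default_design.yaml`) encodes the 15-box set: side lengths 6.8 /
12.3 / 22.4 cm, heights with lid 7.4 / 12.8 / 22.8 cm, and weights

| size   | weights (g)                  |
|--------|------------------------------|
| small  | 114, 235, 455, 649, 1140     |
| medium | 235, 455, 649, 1140, 2199    |
| large  | 455, 649, 1140, 2199, 3808   |

Weights shared between adjacent sizes define the comparison pairs on which
all SWI metrics operate: four small–medium pairs (235–1140 g) and four
medium–large pairs (455–2199 g), i.e. 8 pairs per session, 24 per
participant over three sessions, 744 over a 31-respondent cohort per
condition.

Volumes use the outer dimensions including lid height (e.g.
6.8 × 6.8 × 7.4 = 342.176 cm³), with no wall-thickness correction, and
densities are weight/volume reported half-up at two decimals. The design
anchors density 0.33 g/cm³ in all three sizes (small 114 g, medium 649 g,
large 3808 g). Note that the boxes were only approximately cubic: a few
published densities (small ranks 3–5, and some medium values) differ by
0.01–0.02 from what the nominal dimensions imply, presumably because
measured dimensions differed slightly. The package reports values computed
from the nominal dimensions and does not guess corrected dimensions.

The three session sequences are not part of the published design; they are
generated by a seeded pseudo-random permutation (default seed 20220316,
chosen once from the publication date) purely for reproducibility — no
analysis depends on the ordering, only on the session structure.

## The synthetic observer

`RespondentModel` parameterizes a generative observer used to exercise the
pipeline end to end. It is a stand-in with the qualitative structure the
analysis assumes, **not** an estimate of any real participant.

* **Internal estimate**: `w × bias(size) × exp(ε)`, with `ε ~ N(0, σ²)` and
  `σ² = ln(1 + cv²)` so the multiplicative coefficient of variation equals
  `noise_cv` (default 0.25). Multiplicative log-normal noise reflects that
  weight judgment is ratio-scaled: aggregate judgments are approximately
  linear on a log scale.
* **Size bias** (default small 1.4, medium 1.0, large 0.7, strictly
  decreasing) produces the illusion; the defaults are loosely calibrated so
  that median SWI-factors of simulated cohorts land in the plausible
  0.2–0.9 band, and they are configuration values, not claims.
* **Point judgment**: the internal estimate rounded to a 5 g reporting grid
  (configurable).
* **Interval judgment**: the initial interval is `[e/(1+u), e(1+u)]` around
  one internal draw `e`, with relative half-width `u` (default 0.30), bounds
  rounded outward to whole grams so the width is always ≥ 1 g. Each probe is
  answered by comparing a **fresh** internal draw with the probe, so split
  answers are informative but imperfect — this models within-trial
  perceptual noise and is why the final midpoint tends to be *more* stable
  across sessions than the initial one (successive draws average out).
  A `frozen_percept` flag reuses `e` for all three answers for sensitivity
  analysis.
* **Random responder** (`mode="random"`): point judgments are iid uniform
  draws over a plausible range (default 50–5000 g), interval bounds are two
  ordered uniform draws, probe answers are fair coins. This null observer
  generates the chance baselines: each same-weight comparison is a fair
  coin, so 12 of 24 SWI-cases are expected per respondent, and each
  coin-flip split retains the true weight with probability ½, halving the
  hit rate per split.

Cohorts (`make_cohort`) jitter parameters across respondents with a
dedicated sub-stream of the master seed: illusion strength as a log-normal
exponent on the biases (preserving the small > medium > large ordering),
interval half-width log-normally with σ = 0.5 (clipped to [0.05, 1.0], so
some respondents use very narrow and some very wide intervals), and noise
log-normally with σ = 0.3. Every trial stream is derived from
`(master_seed, respondent seed)`, so a single respondent can be regenerated
in isolation and identical seeds give byte-identical CSV output.

What the generator does **not** emulate: muscle fatigue or holding-time
effects, session-order or learning effects, reference-weight anchoring, and
any coupling between a respondent's point and interval strategies beyond
the shared parameters. Passing tests therefore demonstrate that the
pipeline's metrics behave correctly on data with the assumed structure, not
that the observer model describes human judgment.

## Metrics

* **SWI-case**: within one session, the smaller box of a same-weight
  adjacent-size pair judged *strictly* heavier than the larger. Ties are
  non-cases. Counts are per participant × measure (point, mid1, mid4), out
  of 24 in the default design.
* **Interval non-overlap**: the smaller box's first-interval lower limit
  strictly above the larger box's upper limit — the respondent considers it
  unreasonable that the boxes weigh the same.
* **SWI-factor**: `(j_smaller − j_larger) / min(j_smaller, j_larger)`,
  signed. Factors with |factor| strictly greater than the outlier limit
  (default 10) are flagged excluded; a factor exactly at the limit is kept.
* **pad** (proportional absolute deviation): `|j/w − 1|`; reported as a
  proportion, formatted as a percentage only at the reporting layer.
* **Hit**: true weight *strictly* inside an interval; hit rates are
  reported per split (1–4), both pooled over all trials and as means of
  per-participant rates (the two styles differ and are labelled), and
  optionally by size class.
* **Coverage**: a respondent's point judgment *inclusively* inside their
  own same-session interval from the other condition. The strict/inclusive
  asymmetry between hit and coverage is deliberate and unit-tested at the
  boundaries.
* **Relative SD** (consistency): sample SD (n−1; pinned by the
  350/500/650 → SD 150 anchor) of a respondent's three session judgments of
  one box, divided by their mean. Aggregation is participant-first — mean
  over boxes within each respondent, then cohort mean and paired two-tailed
  t-tests between measures. A pooled alternative is available behind a
  flag; the two coincide on balanced data and differ once series are
  dropped for missing sessions. Interval-limit variability applies the same
  computation to the raw lower/upper limit series.

Descriptive tables use linear interpolation between order statistics for
quartiles and report the smallest modal value with a multimodality flag;
these conventions matter when comparing against published descriptives and
are therefore fixed and documented rather than left to defaults.

Simple regressions are ordinary least squares with the F-test (1, n−2) for
the slope; correlations are Pearson with Fisher-z confidence intervals. No
multiple-testing correction is applied — these are exploratory summaries.
Between-participant confidence intervals in the size-class consistency
table are plain t intervals without within-subject correction, and are
labelled as such.

## Missing data, degenerate inputs, tie-breaks

Comparison pairs with a missing member are skipped with a warning, never
imputed; consistency series require all sessions. Zero-width initial
intervals are rejected (the procedure is undefined on them). Paired t-tests
on zero-variance differences are reported as NaN and flagged. Equal
judgments never count as SWI-cases (strict inequality), and touching
intervals never count as non-overlap.

## Problem sizes

The default synthetic study (31 respondents × 2 conditions × 3 sessions ×
15 boxes = 2790 trials) runs in well under a second. The chance-baseline
checks use 10,000 random responders for the SWI-case expectation (accepted
within 3 standard errors of 12) and 400–500 for the hit-rate halving check
(ratio within 0.08 of 0.5); both sizes give comfortable sampling precision
for the assertions while keeping the full suite fast.

## Known limitations

* The perceptual observer is deliberately minimal: no density cues, no
  reference-weight anchoring, no cross-condition memory, no session drift.
* Cohort-level published statistics (mean pad, hit percentages, the
  printed t and F values) derive from the real participant data and are not
  reproduced by the synthetic cohort; the pipeline emits the same table
  layouts so those analyses can be run externally on real data.
* The mixed-effects modelling of log judgments and the repeated-measures
  ANOVAs are out of scope; tidy per-trial and per-cell tables are exported
  for external fitting.
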