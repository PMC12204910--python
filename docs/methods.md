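# Methods

This note documents the models, numerical choices, and validation logic of
`varens` — what is simulated, how it is estimated, and what the tests do and
do not establish.

## Stimulus and task designs

Every experiment presents nine-item target sets whose values form an exact
arithmetic sequence `mean + k·d`, `k = −4 … +4`, so the set mean is constant
and the iteration difference `d` alone carries variability. Eight levels
`d ∈ {2, 4, …, 16}` are crossed with the condition factor (color channel R/G/B
at mean 130, or mean diameter 100/150/200 px) and repetitions within each
block; block orders are independently shuffled from the design seed.

Preset designs: E1/E2 (color 2-AFC, visual/verbal comparisons, 6 blocks × 48 =
288 trials), E3 (color adjustment, green only, 4 × 32 = 128), E4/E5 (size
2-AFC, 3 × 96 = 288), E6 (size adjustment, 4 × 32 = 128). Visual 2-AFC
comparison sets are five-item sequences at iteration differences 6 (low) and
18 (high); they are centered on the target-set mean — the source designs do
not state the center, and centering on the mean keeps the options informative
about variability only. Adjustment tasks bound the response at [1, 31] (color)
and [0, 24] (size) on a step-1 grid; the counterbalanced high start of the
size task (40) exceeds the ceiling and is clipped on first render. The
adjustment keys' coarse 5-unit step only accelerates navigation, so the model
carries the fine step that determines attainable responses.

Feature bounds (RGB in [0, 255]; size > 0) are enforced as *errors*, not
silent clipping: no preset requires clipping, so a clipped value always
indicates a design bug. Inter-stimulus timing is metadata only; no rendering
is simulated.

## Observer model

The percept of set variability is `v̂ = D(d) + ε`, `ε ~ N(0, σ²)`, floored at
zero. The four distortion families operationalize candidate mechanisms:
veridical; linear `a + b·d` (offset-plus-gain — with `b < 1`, overestimation
at low `d` reversing at `d* = a/(1−b)`); boundary repulsion `d + k·e^(−d/τ)`
(inflation strongest near the "sameness" boundary at `d = 0`; the verbal
mechanism is parameterized here as additive exponential decay); central
tendency `(1−w)·d + w·anchor` (shrinkage toward the mean experienced level,
anchor 9). The model places the bias at the integration stage by fiat; the
behavioral data these tasks produce cannot distinguish encoding, integration,
or decision origins.

2-AFC decisions are criterion-based: "more variable" iff `v̂ > c`, ties broken
by a fair coin, and with probability `lapse` the response is replaced by a
fair coin (standard convention; a replacement, not a flip). The default
criterion is the task's neutral point — the comparison midpoint 12 for visual
2-AFC, the mean stimulus level 9 otherwise. This minimal rule yields a
monotone, approximately logistic psychometric function in `d`; a
comparison-percept race would add parameters without changing that signature.

Adjustment responses are the percept rounded half-even to the response grid
(unbiased under symmetric noise) and clipped to the bounds, independent of the
starting variability: the start is a counterbalanced factor, retained in the
trial records so anchoring models can be added later, but the ideal adjuster
ignores it.

Response times are lognormal, `RT = exp(N(rt_mu − rt_slope·|v̂ − c|,
rt_sigma²))`, so responses far from the criterion are stochastically faster —
the minimal structure needed for median-RT split analyses to be meaningful.

Defaults describe a realistic unbiased participant: `σ = 3` feature units
(implying JND ≈ ln 3·σ/1.7 ≈ 1.9, the scale of human discrimination widths on
these tasks), `lapse = 0.02`, `rt_mu = 6.7` (median ≈ 810 ms), `rt_sigma =
0.35`, `rt_slope = 0.04`. Observer populations may draw any parameter from a
Normal distribution truncated to its legal range. All randomness flows through
`numpy` `Generator` states seeded from `(design.seed, observer.seed)`;
identical seeds give byte-identical trial CSVs.

## Estimation

**Psychometric fits.** Per participant × condition, the logistic model is fit
by maximum likelihood via iteratively reweighted least squares on per-level
aggregated counts (statsmodels GLM/Binomial; tolerance 1e−8, ≤ 100
iterations — aggregation leaves the likelihood unchanged and makes the fit
cheap). Completely separated data (every "less" below every "more") admit no
finite MLE; such fits are flagged non-converged and carry a sign-correct
infinite slope with the PSE at the midpoint between the last all-"less" and
first all-"more" level — the deterministic-observer limit. Single-class data
raise an estimation error. PSE = −β₀/β₁; JND = ln 3/β₁. The JND functional
form is a package choice (75%-threshold half-width); it preserves the ordinal
use of JND as inverse sensitivity and is the convention most common for
2-parameter logistic fits.

**Adjustment fits.** Per participant, ordinary least squares of
`(adjusted − 2)` on `(d − 2)`. The offset-2 coding makes the intercept the
estimated variability at the lowest level actually shown, minus 2; the slope
is unchanged by the offset (affine invariance, tested). Raw per-level mean
adjustments are carried alongside the fit, and per-level percent bias is
computed from those raw means rather than model predictions — at the extremes
of the level range the linear model's prediction and the raw mean can
disagree, and the raw mean is the quantity the bias claims are about.

**Outlier screening.** Tukey fences `[Q1 − k·IQR, Q3 + k·IQR]` with type-7
(linearly interpolated) quartiles, computed per measure within condition
across participants; `k = 3` on {β₀, β₁, PSE, JND} for 2-AFC, `k = 1.5` on
{intercept, slope} for adjustment. A supplementary sign check flags backwards
responders (β₁ < 0), who can otherwise hide inside the fences. Screening
precedes pooling; every exclusion is logged with the triggering measure and
fence.

**Pooling and uncertainty.** Group estimates are a two-stage approximation to
a random-slope mixed model: per-subject ML fits, then unweighted means of the
coefficients; the pooled PSE is −mean(β₀)/mean(β₁). Uncertainty comes from a
seeded percentile bootstrap resampling *subjects* with replacement
(B = 2,000). The two-stage route was chosen over a full crossed
random-effects GLMM deliberately: it is transparent, fast, adequate for
parameter recovery at these designs (validated below), and the bootstrap-CI
emphasis matches how such results are reported; exact agreement with
lme4-style fitters is a non-goal, and the per-subject-fits interface is the
natural adapter point for substituting an external mixed-model fitter.

**Split analyses.** Median-RT splits use each participant's own median
(strictly-below vs rest); experiment-half splits use within-participant
presentation order. Each half is pooled as above; the CI of the PSE
difference uses a paired bootstrap (the same subject resample applied to both
halves). Participants with an empty or single-class half are dropped with a
logged warning.

A note on split-direction logic: central-tendency shrinkage acts on the
*percept* scale, so on the stimulus scale it expands distances from the
anchor — for a criterion `c` and shrink weight `w`, the veridical-observer PSE
moves from `c` to `9 + (c − 9)/(1 − w)`. A second-half PSE that moves *toward*
9 therefore requires a first-half PSE displaced from 9 by some other
distortion and a criterion at the anchor (the verbal task); the split test is
constructed that way.

## Validation and what it shows

The test suite validates against independent oracles and simulation studies:

* the IRLS fitter agrees with an exhaustive profile-likelihood grid search
  (slope grid at 0.005 resolution, intercept profiled by damped Newton —
  globally convergent since the profile is concave) to |ΔPSE| ≤ 0.05 on 50
  random 800-trial datasets;
* 30 linear-distortion observers (`a = 4.23, b = 0.72, σ = 1`) analyzed by
  the adjustment branch recover intercept ≈ 3.67 and slope ≈ 0.72 averaged
  over 200 replicate simulations;
* for an unbiased population (individual criteria Normal(12, 1)), the pooled
  PSE bootstrap CI covers 12 in ≥ 90% of 200 replicates at 30 subjects × 288
  trials, and the mean pooled PSE recovers the criterion within 0.2. The
  calibration population is heterogeneous because a between-subject bootstrap
  is only a meaningful uncertainty measure when subjects vary: with all
  criteria identical the CI collapses toward zero width and the small
  asymptotic bias of fitting a logistic to Gaussian-noise (probit) choices
  over the asymmetric level set (≈ +0.03 at σ = 3) dominates coverage.
  Individual criterion placement varying by about half a JND is the realistic
  condition for a human sample;
* the outlier screen flags a planted grossly insensitive subject (σ = 40) and
  a planted backwards responder in 100% of 100 simulations;
* psychometric monotonicity, byte-level determinism, and CSV round-trip
  identity hold throughout.

Problem sizes (50 × 800 trials; 200 replicates × 30 observers; 100 planted
simulations) were chosen so each study is statistically decisive while the
whole suite runs in about a minute on one CPU.

What passing does **not** show: the generator produces idealized trial
tables — stationary observers, exact lognormal RTs, no sequential
dependencies, no memory decay over the 300-ms item stream, no anchoring to
adjustment start points, no gamma nonlinearity between nominal RGB values and
displayed intensity. Analyses validated here are therefore validated as
*estimators under the stated observer model*, not as claims about any human
dataset; real data in the schema are analyzed identically but inherit none of
these guarantees.

## Degenerate inputs and conventions

Zero-slope (flat) psychometric data leave the PSE undefined (`derive_pse`
raises; near-flat fits produce extreme PSEs that the fences catch). Fewer
than two distinct levels, single-class responses, fewer than 4 participants
for screening/pooling, and mixed response modes in one table are errors, not
warnings. CSV is RFC 4180 UTF-8 with "." decimals; empty cells denote
not-applicable fields; schema violations name the offending column and line.
All seeds are explicit — nothing reads the wall clock.
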