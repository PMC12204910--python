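# varens

Simulation and analysis pipeline for psychophysics experiments on the
perception of **variability in visual ensembles** — sets of similar objects
(circles varying in a color-channel value or in diameter) whose spread an
observer must judge. Human observers systematically *overestimate* ensemble
variability, most strongly when the items are most similar. `varens` packages
the full computational chain needed to study that bias: stimulus-set
construction, synthetic biased observers, two-alternative forced-choice
(2-AFC) and method-of-adjustment task simulation, psychometric fitting,
outlier screening, bootstrap confidence intervals, and percent-bias
quantification. It is aimed at perception researchers who want a tested,
reproducible reference implementation of these analyses — for power analysis,
method validation, or analyzing their own trial tables in the package's tidy
CSV schema.

## The model

A trial shows nine items forming an arithmetic sequence around a fixed mean;
the increment between adjacent items, the *iteration difference* `d ∈ {2, 4,
…, 16}`, operationalizes set variability. A synthetic observer perceives

```
v̂ = D(d) + ε,   ε ~ N(0, σ²)
```

with distortion `D` drawn from four families: veridical (`d`), linear
(`a + b·d`), boundary repulsion from "sameness" (`d + k·e^(−d/τ)`), or central
tendency (`(1−w)·d + w·anchor`). In 2-AFC tasks the observer answers "more
variable" when `v̂` exceeds a criterion (with lapse rate λ); in adjustment
tasks the percept is rounded to the response grid and clipped to the task
bounds.

Analysis fits, per participant, a logistic psychometric function
`P(more) = 1/(1 + e^(−(β₀ + β₁ d)))`, from which

* **PSE** = −β₀/β₁ — the point of subjective equality, and
* **JND** = ln 3 / β₁ — the just-noticeable difference (75%-threshold
  half-width).

Comparing the PSE with the point of objective equality (POE; the midpoint of
the two comparison variabilities, 12, or the mean stimulus level, 9) yields
the percent bias `(estimated − actual)/actual × 100` (positive =
overestimation). Adjustment data are fit per participant by least squares
with offset-2 coding, `(adjusted − 2) ~ (d − 2)`, so the intercept reads out
estimated variability at the lowest level. Group estimates use two-stage
pooling (per-subject fits, unweighted coefficient means) with Tukey-fence
outlier screening (k = 3 for 2-AFC, 1.5 for adjustment, plus a
backwards-responder sign check) and subject-resampling percentile bootstrap
CIs (B = 2,000, seeded).

## Worked example

Thirty observers with a linear perceptual distortion (`a = 4.23`, `b = 0.72`,
`σ = 1`) run through the color adjustment task and its analysis:

```python
from varens import RunConfig, run_pipeline

cfg = RunConfig(
    experiment="E3", n_observers=30,
    observer_spec={"distortion": "linear", "a": 4.23, "b": 0.72,
                   "sigma": 1.0, "lapse": 0.0},
    seed=7, out_dir="varens-demo",
)
result = run_pipeline(cfg)
print(result["pooled"].round(3).to_string(index=False))
```

```
 intercept_offset2  intercept_ci_low  intercept_ci_high  slope  slope_ci_low  slope_ci_high  estimated_at_lowest  n_participants
             3.648             3.597                3.7  0.721         0.716          0.728                5.648              29
```

The pooled offset-2 intercept 3.648 back-transforms to an estimated
variability of 5.65 for sets whose true variability is 2 — a ~180%
overestimation at the lowest level — and the slope 0.721 recovers the
generating gain; one of the thirty subjects was trimmed by the k = 1.5
coefficient screen. The per-level bias table (`result["bias"]`) shows the
signature pattern, from +178% at `d = 2` falling to −1.8% at `d = 16`:

```
 iteration_diff  mean_adjusted  percent_bias_signed
            2.0           5.57               178.45
            4.0           7.15                78.77
            ...
           16.0          15.71                -1.82
```

The same driver handles 2-AFC experiments (`experiment="E1"`), where the
pooled summary carries per-condition PSEs with bootstrap CIs and the bias
table reports both POE conventions.

The command-line interface mirrors the library:

```sh
varens simulate --experiment E3 --n-observers 30 --seed 7 --out sim/
varens analyze --trials sim/trials.csv --bootstrap-b 2000 --out analysis/
varens report --in analysis/
```

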