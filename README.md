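# metamem

Three-level random-effects meta-analysis of total sleep deprivation's
effect on learning and memory — and a general toolkit for meta-analyses of
clustered standardized mean differences.

Experiments on sleep deprivation and memory typically report several
correlated effect sizes per publication (multiple tasks, conditions, or
test sessions). `metamem` implements the complete analysis workflow for
such literatures:

- **Effect sizes** — Cohen's *d*<sub>s</sub> for independent-groups designs
  (pooled SD) and *d*<sub>av</sub> for within-subject designs (average of
  the condition SDs), bias-corrected to Hedges' *g* with
  *J* = 1 − 3/(4·df − 1), with a consistent sign convention (positive *g* =
  deprivation impaired performance).
- **Three-level model** — for effect *i* in report *j*,
  *y*<sub>ij</sub> = **x**<sub>ij</sub>′β + *u*<sub>j</sub> + *w*<sub>ij</sub> + *e*<sub>ij</sub>
  with *u*<sub>j</sub> ~ N(0, τ²<sub>between</sub>),
  *w*<sub>ij</sub> ~ N(0, τ²<sub>within</sub>) and known sampling variances
  *v*<sub>ij</sub>; variance components estimated by REML, coefficients by
  GLS, with Wald and one-sided likelihood-ratio inference and categorical /
  continuous moderator meta-regression.
- **Heterogeneity** — Cochran *Q*, the multilevel *I*² decomposition
  (sampling / within-report / between-report shares of total variance), and
  *t*-based 95% prediction intervals.
- **Publication bias** — a multilevel variant of Egger's regression
  (standard error as a moderator in the three-level model) and
  Duval–Tweedie trim-and-fill (L0/R0 estimators) with an adjusted pooled
  estimate.
- **Influence diagnostics** — studentized deleted residuals, Cook's
  distance and DFBETAS from full leave-one-out refits.
- **Power** — noncentral-*t* achieved power per study and sample-size
  solving (exact noncentral-*t* or large-sample normal approximation).
- **Quality scoring** — a 22-item methodological checklist aggregated into
  reporting / bias / confounding / power cluster subscores.
- **Synthetic literatures** — a generator that emulates the clustered
  structure, design mix and study sizes of this literature, with optional
  significance-based publication selection, so every stage is testable
  without any data download.

## Worked example

```python
from metamem import (SimulationSpec, simulate_dataset, fit_three_level,
                     heterogeneity_report, wald_inference)

# a literature like the after-learning one: 45 reports, ~130 effects,
# true pooled effect 0.277, tau2_between .061, tau2_within .026
ds = simulate_dataset(SimulationSpec(seed=5))
fit = fit_three_level(ds)
inf = wald_inference(fit)
het = heterogeneity_report(ds, fit)
print(f"pooled g = {fit.estimate:.3f} "
      f"[{inf.ci_low[0]:.3f}, {inf.ci_high[0]:.3f}]")
print(f"tau2_between = {fit.tau2_between:.3f}, "
      f"tau2_within = {fit.tau2_within:.3f}")
print(f"Q({het.df}) = {het.Q:.1f}, I2 = "
      f"{het.i2_sampling:.0f}/{het.i2_within:.0f}/{het.i2_between:.0f}")
print(f"95% PI = ({het.pi_low:.3f}, {het.pi_high:.3f})")
```

prints

```
pooled g = 0.283 [0.186, 0.379]
tau2_between = 0.054, tau2_within = 0.024
Q(130) = 238.8, I2 = 55/14/31
95% PI = (-0.280, 0.846)
```

The pooled estimate recovers the simulated truth of 0.277 within its
confidence interval; the *I*² line says 55% of observed variation is
sampling error, 14% sits between effects within the same report, and 31%
between reports; the prediction interval is the range in which the true
effect of a new study would fall 95% of the time.

The same analysis runs from the shell on any CSV effect-size table:

```sh
metamem simulate --out lit.csv --seed 42
metamem run --data lit.csv --out results/
metamem power --d 0.277 --design within --solve-n
```

`metamem run` writes `report.json` plus forest, funnel, influence and
power tables; the pipeline follows the standard order (overall fit →
heterogeneity → publication bias → outlier/influence screening → refit and
moderator analyses on the cleaned set).

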