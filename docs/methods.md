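# Methods

## The model

Observed effects are Hedges' *g* values clustered by report. For effect
*i* in report *j*:

    y_ij = x_ij' beta + u_j + w_ij + e_ij
    u_j  ~ N(0, tau2_between)      # level 3: between-report heterogeneity
    w_ij ~ N(0, tau2_within)       # level 2: within-report heterogeneity
    e_ij ~ N(0, v_ij)              # level 1: sampling error, v_ij known

The marginal covariance is block-diagonal: within report *j*,
`M_j = diag(v) + tau2_within I + tau2_between 11'`. The restricted
log-likelihood maximised over the two variance components is

    l_R = -1/2 [ (k - p) log 2pi + log|M| + log|X' M^-1 X| + r' M^-1 r ]

with `r` the GLS residuals at the profiled coefficients. All solves use
the Sherman–Morrison identity on the rank-one cluster blocks, so a
likelihood evaluation is O(k); this is verified in the tests against a
dense-matrix implementation with explicit inverses and log-determinants,
and the optimum is verified against a 2-D grid search at 1e-3 resolution.

A note on level naming: levels are numbered sampling error (1),
within-report (2), between-report (3), the conventional ordering for
three-level meta-analysis. Some published descriptions of this design
label between-study variance "level 2"; only the names differ, not the
model.

### Numerical choices

- **Optimiser.** Bounded L-BFGS-B directly on (tau2_between, tau2_within)
  with lower bounds at 0, multi-started from the 3x3 grid
  {0, v_typ/2, v_typ}^2 where v_typ is the typical sampling variance.
  Boundary solutions (a component exactly 0) are legitimate and common, so
  the parameterisation must include 0 exactly — this is why the variances
  are not optimised on the log scale. Convergence tolerance `reml_tol`
  (default 1e-8) on the objective.
- **Inference.** Wald z tests and normal-quantile CIs for coefficients
  (matching standard multilevel meta-analysis reporting; no Knapp–Hartung
  adjustment, which this workflow does not use). Moderator omnibus tests
  are Wald chi-square on the non-intercept block. Variance components are
  tested by one-sided REML likelihood-ratio tests with the 50:50
  boundary mixture, p = 0.5 P(chi2_1 > LRT); the unhalved tail is also
  reported.
- **Degenerate inputs.** Zero pooled SD, df < 2, constant standard errors
  (Egger), all-zero quality totals, and k below the minimum for each
  statistic raise typed errors rather than returning NaN.
- **Moderator coding.** Categorical moderators use treatment coding with
  the alphabetically first level as reference (overridable); numeric
  moderator values are entered as continuous covariates. Moderators with
  more than two categorical levels must be recoded explicitly — silent
  multi-column expansion is deliberately not done, to keep the omnibus df
  transparent.

## Effect sizes

Between designs: `d_s = (m1 - m2)/s_pooled`,
`v = (n1+n2)/(n1 n2) + d_s^2/(2(n1+n2))`, df = n1+n2-2. Within designs:
`d_av = m_diff / ((sd1+sd2)/2)`, `v = (1/n + d_av^2/(2n)) * 2(1-r)`,
df = n-1, where r is the cross-condition correlation. Primary studies
rarely report r, so it is configurable with default r = 0.5 — the neutral
choice at which the within-design variance equals the per-observation
variance of a between design, making the default conservative rather than
flattering to within designs. Both estimates are bias-corrected with
J = 1 - 3/(4 df - 1), applied to the variance as J^2 (first-order delta
method). Orientation: positive g always means deprivation impaired
performance; "lower is better" outcomes (reaction times) are sign-flipped,
never silently assumed.

Conversion from reported F or t statistics is out of scope: such effects
enter as precomputed (g, v) records.

## Heterogeneity

Residual Cochran Q uses fixed-effect weights 1/v and the model's design
matrix (QE form). The multilevel I^2 splits
`tau2_within + tau2_between + v_typ` into percentage shares, with
`v_typ = (k-1) sum(w) / ((sum w)^2 - sum(w^2))`; the three shares sum to
100 by construction. Prediction intervals are
`mu +/- t_{k-2} sqrt(se^2 + tau2_within + tau2_between)`: a new study
draws both random terms, so both components enter; the t distribution on
k-2 degrees of freedom follows the Higgins-style convention, which also
reproduces published intervals computed from rounded summary inputs to
within 0.001.

## Publication bias

The Egger variant enters each effect's standard error as a continuous
moderator in the three-level model and reads the Wald z of its slope, so
the asymmetry test inherits the clustered error structure. Trim-and-fill
follows Duval & Tweedie: iterate {fixed-effect centre on the retained
set -> rank-based k0 estimate (L0 default, R0 optional) -> trim the k0
most extreme effects on the heavy side} to stability, then mirror the
trimmed effects about the final centre and re-estimate with a two-level
DerSimonian–Laird random-effects fit on observed + imputed. Trim-and-fill
assumes independent effects, so the adjusted estimate is deliberately
two-level — a sensitivity analysis, not a replacement for the multilevel
fit. The implementation reproduces metafor's `trimfill` exactly on a
constructed 8-point example (k0, adjusted estimate, SE and tau2). The
trimming side defaults to "auto": opposite the sign of the funnel slope.

Two caveats the tests make explicit. First, the rank-based k0 estimator
only detects suppression of the *most extreme* one-sided effects; smooth
one-sided truncation of a wide symmetric set can yield k0 = 0 (metafor
agrees on the same data). Second, because the sampling variance of a
standardized mean difference contains d^2/(2n), the computed standard
error is mechanically correlated with the effect itself, and the Egger
test is anticonservative when the true pooled effect is far from zero and
heterogeneity is present — with z-based inference its size is near
nominal only for a homogeneous zero-mean literature, which is the null
the size test uses. Both are properties of the published methods, not of
this implementation.

## Influence diagnostics

All diagnostics come from full leave-one-out refits (both variance
components re-estimated; no hat-matrix approximations): studentized
deleted residuals standardise y_i against the model fitted without it,
using the full predictive SD
`sqrt(v_i + tau2_w(-i) + tau2_b(-i) + x_i' Var(beta(-i)) x_i)`, flagged at
|t| > 3; Cook's distance is
`(beta(-i) - beta)' Var(beta)^{-1} (beta(-i) - beta)`; DFBETAS are
`(beta_j - beta_j(-i)) / se(beta_j(-i))`. No universal Cook's threshold
exists for meta-analysis, so the default flag is the metafor-style
heuristic D > median(D) + 6 IQR(D), with an absolute-cutoff option; the
rule is configuration, not a constant buried in code. With k = 2 the
leave-one-out quantities are meaningless and flags are suppressed with a
warning. The pipeline removes flagged effects before all moderator
analyses (disable with `--keep-influential`).

## Power

Achieved power uses the noncentral t distribution (between:
ncp = d sqrt(n1 n2/(n1+n2)), df = n1+n2-2; paired: ncp = d_z sqrt(n),
df = n-1; both rejection tails counted), validated against direct
Monte-Carlo simulation of t tests at 1e6 replicates. Sample-size solving
offers two paths because both are in wide use: the exact noncentral-t
solver, and the large-sample normal approximation
`n_per_group = 2 (z_{1-a/2} + z_{power})^2 / d^2` behind many planning
calculators. For d = 0.277 they give between-subject totals of 410
(normal) vs 412 (noncentral-t), and for d = 0.621, 82 vs 84; paired-design
solutions (105 and 23 pairs) use the exact path. For paired designs the
standardized effect is interpreted as d_z, consistent with how paired
t-test power calculators parameterise it. For far-tail regimes where
scipy's noncentral t loses precision, the negligible wrong-side tail is
dropped and the dominant tail falls back to its normal limit.

## Synthetic literatures

The generator draws, per report, a random intercept u_j, a design
(between with probability 104/130, matching the observed design mix), and
a total sample size from a truncated normal (mean 31.84, SD 13.15, range
6–78, matching the observed distribution; split into equal groups for
between designs, the number of pairs for within designs). Each of 1–5
effects per report adds w_ij and any moderator shifts, and raw normal
scores (bivariate with correlation r_within for paired designs) are
simulated and summarised — so the effect-size module, not an injected g,
is always on the tested path. Defaults are the after-learning literature
scale: 45 reports, ~130 effects, mu = 0.277, tau2_between = 0.061,
tau2_within = 0.026. Moderator level frequencies default to the observed
ones (recovery sleep 85:45, declarative:procedural 109:21, and so on)
with zero true shifts unless specified. Optional selection removes each
nonsignificant effect (two-sided p >= threshold) with a given
probability, at the effect level, emulating selective reporting of
individual results; report-level selection can be composed from it.

What the generator does **not** emulate: non-normal outcome
distributions, unequal group allocation, correlated moderators, rounding
and extraction error in published summaries, or dependence of the design
choice on the expected effect. Passing recovery tests therefore show the
estimators are correct under the model's own assumptions at realistic
scale — not that real extraction pipelines are error-free.

Calibration facts the tests establish under these defaults: pooled-
estimate bias below 0.02 with 95% CI coverage in [92%, 97%] over 500
replicates; a small downward shrinkage of the pooled SMD (about -0.01 to
-0.015) is expected and real, caused by the mechanical correlation
between estimated effects and their 1/v weights, and is inherited from
the standard method rather than introduced here.

## Quality scoring

Totals over 22 binary items are normalised by the dataset maximum (the
best study anchors 1.0), and items aggregate into reporting / bias /
confounding / power cluster proportions. The item-to-cluster map ships as
an editable YAML data file with cluster sizes 6/7/6/3; the assignment is
provisional — instruments of this family define clusters in supplementary
materials, so the map is data, not code. The power cluster is computed
but excluded from default moderator sets, since most studies score zero
on it.

## Sizes used by the test suite

Oracle comparisons run on literatures of 6–12 reports (dense-matrix and
grid-search REML), size and recovery simulations on 45–80 reports with
500 replicates for recovery and 1000 for the Egger size check, and power
validation on 1e6-replicate Monte-Carlo t tests — sizes chosen so the
whole suite completes in a few minutes while keeping Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- No robust (cluster-robust / sandwich) standard errors and no
  Knapp–Hartung small-sample adjustment; z-based Wald inference is mildly
  liberal for moderator slopes at few clusters.
- Trim-and-fill inherits its known weaknesses (independence assumption,
  insensitivity to smooth truncation, instability under heterogeneity);
  selection models (PET-PEESE, 3PSM) are out of scope.
- Multi-level categorical moderators require explicit dichotomisation.
- F/t-to-d conversion is not provided.
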