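# Methods

## Structural models and scenarios

Each simulated replicate draws, in causal order, a binary covariate
`U ~ Bernoulli(π_U)`, a continuous exposure
`A ~ N(α₀ + α_U·U, σ_A²)`, a missingness indicator `R_A` for the exposure
(0 = missing), and a continuous outcome
`Y ~ N(γ₀ + γ_U·U + γ_A·A + γ_UA·U·A, σ_Y²)`. The missingness law is
either logistic, `P[R_A = 0] = expit(β₀ + β_U·U + β_A·A + β_UA·U·A)`, or
the deterministic extreme `R_A = 1 − U`, under which the exposure is
missing exactly when `U = 1`. The observable exposure `A*` equals `A` where
`R_A = 1` and is missing otherwise; the complete `A` column is retained
internally only for benchmarking.

Scenarios are the possible edge sets of the missingness diagram: which of
`U` and `A` point into `R_A`, crossed with whether `U` confounds the
exposure–outcome relation (`α_U ≠ 0`) and whether `U` is available to the
analyst (`u_observed`). The classifier in `dgm.classify_scenario` derives
the label (i)–(vi) from the parameter zero-pattern:

- (i) no edges into `R_A`, no confounding — MCAR;
- (ii)/(iii) `U → R_A` only, without/with confounding (the deterministic
  mechanism is the extreme of this edge);
- (iv)/(v) `A → R_A`, alone / together with `U → R_A`, no confounding;
- (vi) everything else.

Patterns that do not match any of the five constrained diagrams — e.g.
confounding with purely random missingness, which the factorial grid does
produce — are assigned to the unconstrained catch-all (vi). The `β_UA`
interaction opens both the `U → R_A` and `A → R_A` edges.

## Intercept solving

Intercepts are functions of the other parameters, not free dials:
`α₀ = −α_U·π_U` (so `E[A] = 0`),
`γ₀ = −(γ_U·π_U + γ_A·E[A] + γ_UA·π_U·(α₀ + α_U))` (so `E[Y] = 0`), and
`β₀` solves `P[R_A = 0] = target` where the marginal probability is the
two-component mixture over the `U` strata of one-dimensional Gaussian
integrals of the expit. Those integrals are evaluated by 64-node
Gauss–Hermite quadrature (the integrand is an expit against a Gaussian
kernel; 64 nodes put the quadrature error far below the 1e−6 tolerance,
which the test suite verifies against an adaptive integrator). The root in
`β₀` is found by a Newton iteration safeguarded by bisection on the bracket
[−40, 40]; the marginal probability is strictly increasing in `β₀`, so the
root is unique, and solutions are cached because a factorial grid revisits
the same slope combination many times. Residuals at the returned root are
below 1e−10.

## Analyses

Complete-case analysis regresses `Y` on `A*` among rows with `R_A = 1`.
Imputation fits a linear model of `A` on `Y` (plus `U` and `U·Y` when the
covariate is observed — the interaction is always included so the
imputation model is at least as rich as any analysis model it feeds) among
complete rows, then draws `m = 5` completed datasets by proper imputation:
`σ² ~ scaled-inv-χ²(df, s²)`, `φ ~ N(φ̂, σ²·(XᵀX)⁻¹)`, missing values from
`N(xᵀφ, σ²)` — the canonical Bayesian construction under the
noninformative prior. No predictive-mean matching is used; with a single
incomplete variable the joint-normal and conditional-regression
formulations coincide, and the conditional form is implemented.

The three imputation-based outcome models add, successively, nothing, the
missing-indicator main effect `(1 − R_A)`, and its interaction
`A_imp·(1 − R_A)`. The indicator is coded `1 − R_A` in **both**
indicator models, so the indicator coefficient `γ̂_R` has the same meaning
(the penalty/offset attached to *imputed* rows) across models; the
interacted parameterisation spans the same column space as coding the main
effect on `R_A`, only the sign and intercept of `γ̂_R` change. A useful
algebraic identity follows from the full interaction: the fully interacted
model fits observed and imputed rows separately, so its exposure
coefficient reproduces the complete-case estimate exactly — the test suite
asserts this.

Per-imputation fits are pooled by Rubin's rules: pooled estimate = mean,
total variance `T = W + (1 + 1/m)·B`, confidence intervals from a t
distribution on **Barnard–Rubin adjusted** degrees of freedom (the
small-sample formula, with the complete-data df taken as the smallest
residual df among the fits). With `B = 0`, the df falls back to the
complete-data df; a single imputation is pooled as `T = W` and flagged.
Single fits (complete case, completed data) use t intervals on their
residual df. Which df rule produced published coverage figures is not
derivable from the study description; these choices are recorded in the
run-metadata sidecar.

### Aliasing and failures

Structural aliasing is expected, not exceptional: under `R_A = 1 − U` the
covariate is constant among complete rows; with zero missing rows the
indicator columns are constant. Designs are reduced to a maximal linearly
independent column set (earlier columns kept in preference to later ones)
and the dropped names are recorded on the fit, so the replicate still
contributes to the grid instead of failing. Replicates where every
exposure value is observed or every value is missing are flagged and
never regenerated (regeneration would bias the design); downstream fits
that genuinely cannot proceed are recorded as failure rows, and summaries
report failure counts in an explicit column rather than silently shrinking
denominators.

## The factorial grid

Defaults reproduce the full study design: `α_U, β_A, γ_U ∈ {0, 0.1, 0.5, 1}`,
`β_U ∈ {−1, 0, 0.1, 0.5, 1}`, `β_UA, γ_UA ∈ {0, 0.5}`,
`σ_Y ∈ {0.1, 0.5, 1}`, `P[R_A = 0] ∈ {0.25, 0.5, 0.75}`, with `γ_A = 1`,
`σ_A = 1`, `π_U = 0.5`, `n = 10,000` fixed — 11,520 cells — plus the
deterministic stratum, which drops the redundant `β` slopes and varies
`π_U ∈ {0.25, 0.5, 0.75}` instead (missingness there *is* the covariate
prevalence) — 288 cells, 11,808 in total. Every cell is analysed both with
the covariate hidden and with it observed; the `u_observed` flag on a
configuration records which variant a scenario label refers to.

Per cell and analysis, the retained summaries are the
2.5/25/50/75/97.5th percentiles of the estimates (linear interpolation
between order statistics), the mean and median, the empirical SE (SD of
estimates across replicates), the mean model-based SE, the mean CI length,
and the coverage of the target value (default 1 for the exposure
coefficient; the analytic module supplies `δ_A = γ_A + π_U·γ_UA` per cell
when conditional targets are wanted).

### Seeding and parallelism

The stream for replicate `r` of cell `c` under study seed `s` is
`SeedSequence([s, c, r, stage])`, with separate stages for data generation
and each imputation variant. Summaries are therefore invariant to cell
reordering and to the number of parallel workers, which the tests assert.

## Analytic oracles

Two closed forms anchor the simulations. The standardized causal effect
`δ_A = γ_A + π_U·γ_UA` (between the conditional effects `γ_A` and
`γ_A + γ_UA`, nondecreasing in `π_U` for `γ_UA ≥ 0`). And, in the
deterministic-missingness case without interaction, the expectation of the
indicator coefficient in the indicator-augmented model:
`γ_U·σ_Y² / (γ_A²·σ_A² + σ_Y²)` — the covariate effect attenuated by
regression dilution, because the imputed exposure is a noisy proxy built
from the outcome; the exposure coefficient itself remains unbiased. The
formula is embodied as a testable prediction and verified against the
simulation within Monte-Carlo bands (its error order in `n` is not
characterised; tests do not assert exact equality).

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: Gaussian exposure
and outcome, a single binary covariate, exactly one incomplete variable,
logistic or deterministic missingness, solved intercepts. It does not
emulate features of real routinely collected data — multivariate
missingness patterns, non-normal or categorical exposures, multiple or
continuous confounders, measurement error — so passing tests demonstrate
correctness of the estimators under the stated structural models, not
robustness on real health records.

## Problem sizes

Full-grid reproduction (11,808 cells × 200 replicates) is a cluster-scale
run. The bundled checks use the study's per-cell conditions — 200
replicates of n = 10,000 with five imputations — for the focal cells, and
a stratified 20-cell subsample at 50 replicates as an end-to-end smoke
test; unit tests use smaller n where only code paths, not Monte-Carlo
precision, are at stake. Monte-Carlo acceptance bands are three standard
errors of the replicate mean.

## Known limitations

- The scenario classifier is total (every zero-pattern gets a label), so
  diagram labels for patterns outside the six canonical ones are a
  convention (catch-all (vi)).
- Barnard–Rubin df and the linear percentile rule are conventions where
  the study description is silent; both are recorded in output metadata.
- The deterministic stratum fits the covariate-adjusted analyses with the
  covariate aliased out among complete rows; results for those cells
  reflect the reduced designs (dropped columns are recorded).
- Proper imputation assumes the linear imputation model; no
  predictive-mean matching or robustness variants are provided.
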