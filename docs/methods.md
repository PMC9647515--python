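# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the limitations of the package.

## Data model and validity rules

An ESM dataset is a two-level structure: beeps (level 1) nested in
subjects (level 2). Each beep row carries the scheduled and completed
timestamps, the three momentary composites — stress (X), negative affect
(M), psychotic experiences (Y), each on a 1–7 scale — and the subject-level
group (control / relative / patient), age and gender. The package accepts
precomposed composites only; item-level scoring is out of scope.

Validity follows standard ESM practice:

- **Lateness**: a report completed *later than* 15 minutes after the
  signal is invalid. The boundary is read strictly, so a delay of exactly
  15 minutes is kept. Reports completed before the signal are flagged
  invalid with a warning rather than an error. Invalid records stay in the
  container but are excluded from every analysis; the filters are monotone
  and idempotent.
- **Compliance**: subjects with fewer than one third of the *scheduled*
  beeps valid (design: 10 beeps/day × 6 days = 60) are dropped entirely;
  exactly one third is retained ("at least").
- **Item-level missingness**: a beep missing one composite remains usable
  for analyses not involving that composite; each model equation uses its
  own available cases (the missing-at-random assumption, conditional on
  the variables in the model).

**Lagged pairs** are formed only from immediately adjacent valid beeps
within the same subject-day. An invalid intermediate beep breaks the
chain, and overnight transitions never pair, so every pair spans one
nominal ~90-minute sampling interval. Carrying lags across gaps would
silently change the lag duration the coefficients refer to.

**Aggregates** are person means over valid beeps; group comparisons are
Welch two-sample tests on person means with 95% confidence intervals
(the conventional choice for unequal group variances; reported as such in
the output). With a single subject per group the point difference is
still reported but the interval is undefined.

## Two-level estimation core

All regressions are linear mixed models with subject random intercepts
(optionally random slopes), estimated by **maximum likelihood, never
REML**, so log-likelihoods, AIC and BIC are comparable across mean
structures. Estimation is delegated to statsmodels `MixedLM`; several
optimizers are tried in sequence (BFGS first) and candidate fits with
non-finite likelihoods are rejected — a guard against optimizers that
report convergence at a spurious boundary. A model with no random effects
reduces to pooled OLS, which is the closed-form oracle used in tests.

Degrees of freedom count fixed effects, the free elements of the
random-effect covariance, and the residual variance; AIC = −2ℓ + 2k and
BIC = −2ℓ + k·log(n_obs) are computed from that count uniformly across
engines. Variance components are constrained non-negative by `MixedLM`'s
parameterization; estimates within 1e−6·σ² of zero raise a boundary
warning, not an error. Rank deficiency is detected on the patsy design
matrix before fitting and reported with the offending columns.

An optional **subject-clustered sandwich covariance** for the fixed
effects is computed from the fitted marginal covariance
V_i = Z_i G Z_i′ + σ²I: bread A = Σ X_i′V_i⁻¹X_i, meat = outer products of
the per-subject GLS scores X_i′V_i⁻¹r_i. When the model is exactly true
and balanced it agrees with the model-based covariance up to sampling
noise; it is an approximation to robust-ML standard errors, not a
replication of any particular software's implementation.

Model comparison reports ΔAIC/ΔBIC always; likelihood-ratio statistics
only when the caller asserts nesting (no automatic nesting detection),
and refuses to compare fits on different observation sets.

## Cross-sectional moderated mediation

Per direction (X→M→Y, or Y→M→X with roles swapped), three equations are
fitted on the valid beeps, all with subject random intercepts and the
age and gender covariates:

1. mediator: `M ~ X*W + age + gender`
2. outcome: `Y ~ X*W + M*W + age + gender`
3. total: `Y ~ X*W + age + gender`

W is dummy-coded with controls as reference; each group's path is the
reference coefficient plus its interaction, with covariances obtained by
the corresponding linear transform. The conditional indirect effect is
the product of fixed effects a_g·b_g (the product-of-coefficients
strategy); no random-slope covariance correction is applied, and because
the equations are fitted separately the joint coefficient covariance is
block-diagonal — the a–b sampling covariance is zero by construction. A
jointly estimated stacked-equation system would allow a nonzero a–b
covariance and is a documented extension point, not implemented.

P_M = indirect/total, reported unclipped with a suppression flag when the
direct effect opposes the indirect effect in sign; a zero total effect
leaves P_M undefined. Group contrasts of conditional indirect effects are
differences of products with Monte Carlo intervals over the joint
(block-diagonal) coefficient distribution.

Predictors enter raw by default; person-mean centering is available as a
flag (`center_within`) since the within/between decomposition is a
genuinely open modelling choice in 1-1-1 designs and the random intercept
already absorbs between-person level differences. Random a/b slopes are
optional (`random_slopes`); which paths carried random slopes in the
motivating analyses is unknown, so random-intercept-only is the default.

## Monte Carlo confidence intervals

For any smooth function of coefficients — product, difference of
products, linear combination — the sampling distribution is approximated
by drawing from N(θ̂, V̂) and taking empirical α/2 and 1−α/2 percentiles
of the transformed draws. Percentile (not bias-corrected) intervals are
used, the standard choice for multilevel indirect effects. Defaults:
20 000 repetitions (endpoint Monte Carlo noise well below the third
decimal at typical coefficient scales), α = 0.05. Each interval consumes
a fresh child seed derived from the engine seed and a call counter, so a
batch of intervals is reproducible end to end while individual intervals
remain independent. The covariance is validated for symmetry and positive
semi-definiteness; draws use the eigendecomposition method, which
tolerates exactly singular covariances (e.g. a coefficient known with
certainty).

## Half-longitudinal cross-lagged panel models

On the lagged-pair frame (complete cases across all six lag/outcome
columns plus covariates, so all variants see identical data), the
variants fit these equation sets, every lagged predictor interacted with
group and each equation carrying subject random intercepts:

| variant | M_t regressors | Y_t regressors | X_t regressors |
|---|---|---|---|
| ar | M_{t−1} | Y_{t−1} | X_{t−1} |
| forward | M_{t−1}, X_{t−1} | Y_{t−1}, M_{t−1}, X_{t−1} | X_{t−1} |
| reverse | M_{t−1}, Y_{t−1} | Y_{t−1} | X_{t−1}, M_{t−1}, Y_{t−1} |
| comprehensive | all three | all three | all three |

These are the minimal regressor sets that identify the half-longitudinal
paths while controlling each outcome's prior status; the variants are
nested (ar ⊂ forward/reverse ⊂ comprehensive), which the likelihood
ordering tests exploit. The forward indirect effect is axm·bmy
(X_{t−1}→M_t times M_{t−1}→Y_t), the reverse aym·bmx, each with Monte
Carlo intervals and group contrasts as in the cross-sectional case. The
"total" lagged effect reported alongside comes from a no-mediator
companion equation (e.g. `Y_t ~ (Y_{t−1} + X_{t−1})*W + age + gender`).
Group moderation applies to autoregressive paths as well, so per-group AR
coefficients are reported.

Random slopes on the lagged predictors are optional; on non-convergence
the fit downgrades to random intercepts with a logged warning.
Lagged pairs are treated as exchangeable level-1 units; no
continuous-time decay adjustment for heterogeneous lag durations is made.
Contemporaneous residual covariances among X_t, M_t, Y_t are not
modelled (the equations are fitted separately).

## Synthetic data generator

The generator is the package's ground-truth test bed. Per subject it
draws random intercepts for (X, M, Y) from a configurable covariance
(optionally random a/b slopes), then simulates beeps in time order within
each day from

- AR(1) terms (ρX, ρM, ρY), cross-lags (axm, bmy, aym, bmx, dxy, dyx),
- and a contemporaneous recursive mediation chain in **one** causal order
  per dataset — X→M→Y or Y→M→X; configuring both at once would be cyclic
  and is rejected.

Each day restarts the lag state with a short burn-in (3 steps), so
dynamics are near-stationary within days and nothing carries overnight,
matching the pairing rule. Latent values are shifted to group target
means, covariate effects added, and clipped to [1, 7] by default;
clipping can be disabled for exact-recovery tests (the container then
skips its scale check). Default means and spreads are placed ≥ ~2 s.d.
from the scale bounds so clipping is rare (<~3% of values) and estimator
bias from censoring is negligible relative to the test tolerances.

Beep schedules follow the design: one uniform draw per 90-minute block in
a 07:30–22:30 window, 10 beeps/day for 6 days. Missingness is **MAR given
group and covariates** (a logistic model in group and age; never in the
momentary values themselves), and answered reports get exponential delays
(mean 7 min), so roughly 10% of responses additionally fail the 15-minute
rule — overall ~70% valid beeps, a realistic compliance level. Default
group sizes are 244/165/245 (controls/relatives/patients).

One root seed fans out to an independent stream per subject
(`SeedSequence.spawn`), so identical seeds give identical datasets and
subject-level reproducibility survives reordering.

Scenario presets:

- `null_mediation` — a = 0 everywhere (b = 0.4, c′ = 0.2), no dynamics;
  for type-I-error and coverage studies.
- `paper_like_cross_sectional` — pure contemporaneous Y→M→X chain with
  per-group true indirect effects 0.355 / 0.323 / 0.208
  (controls/relatives/patients) and positive direct paths giving
  P_M ≈ 0.65–0.68. Dynamics are zero in this preset: it encodes exactly
  the assumptions of the cross-sectional estimator, which is what makes
  it a clean recovery benchmark.
- `paper_like_longitudinal` — cross-lag-only dynamics (ρ = 0.4,
  small group-ordered cross-lags, near-trivial indirect effects) with
  contemporaneous paths zero. With both contemporaneous mediation and AR
  dynamics active, lagged-equation coefficients would no longer equal
  the configured cross-lags, so the preset keeps the two mechanisms
  separate to preserve the meaning of the recorded ground truth.
- `suppression` — direct effect opposite in sign to the indirect effect
  (a = 0.4, b = 0.4, c′ = −0.08), so P_M > 1 with the suppression flag.

No attempt is made to reproduce any real pooled dataset's exact
distributions; magnitudes are chosen for test power and realism of scale.
What passing tests show is that the estimators recover the structure they
assume at realistic sizes and noise levels — not that real ESM data meet
those assumptions (real data have floor effects, skewness, item-level
missingness and lag heterogeneity the generator only partially emulates).

## Pipeline and reproducibility

`run_pipeline` executes load/simulate → filters → aggregates → both
mediation directions → lagging → AR and CLPM variants → model comparison,
writing CSV/JSON tables, fixed-width text tables (3 decimals; p-values
below 0.0005 printed "<0.001"; suppressed P_M footnoted; undefined cells
"n/a"), and a manifest with package/library versions, the seed, a
canonical config hash and a hash of all rendered tables. The global seed
fans out to named per-stage child seeds (simulation, each Monte Carlo
engine), so partial re-runs reproduce and two runs with identical config
and seed produce identical manifests. Stage failures abort with the stage
name; artifacts written before the failure are preserved.

## Problem sizes used in the test and acceptance suites

Statistical property checks run on deliberately modest simulation sizes
chosen so the whole suite completes quickly while keeping Monte Carlo
error small relative to each tolerance: indirect-effect recovery uses 40
replicates of 50 subjects/group (estimation error ≈ 0.01 against a ±0.05
tolerance), interval calibration uses 2000 replicates with 5000 draws per
interval, AR recovery uses 200 subjects × 54 pairs, and longitudinal null
behaviour uses 24 replicates of ~55 subjects. The acceptance script uses
similar sizes and records each quantity's `n`.

## Known limitations

- Separate-equation estimation (no joint FIML across equations); the a–b
  sampling covariance is fixed at zero in the Monte Carlo step.
- No REML, crossed random effects, >2 levels, or Bayesian estimation.
- No three-wave (full) cross-lagged mediation design, no continuous-time
  models, no multiple mediators, no 2-1-1/2-2-1 person-level mediation.
- The sandwich covariance approximates robust-ML inference; exact
  numerical equivalence with other mixed-model software is not a goal.
- The 1–7 clipping in the generator mildly attenuates paths when means
  sit near the scale bounds; presets avoid this regime, real data may not.
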