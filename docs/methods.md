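# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices and the limits of what the test suite demonstrates.

## Prediction model and pooling

The prediction model is a GLM `E[y] = h(x'beta)` with identity or logit
link, fitted by maximum likelihood to each of `M` imputed datasets.
Gaussian models are solved by least squares with the exact OLS covariance;
logistic models by IRLS (statsmodels GLM, max 100 iterations, deviance
tolerance 1e-8).  Rubin's rules give the pooled coefficients
`beta_bar = mean_k beta^(k)`, within-variance `W` (mean covariance),
between-variance `B` (sample covariance over imputations, denominator
`M - 1`, zero when `M = 1`) and total `T = W + (1 + 1/M) B`.  Rubin degrees
of freedom `(M - 1)(1 + W/((1 + 1/M)B))^2` are stored per term for honest
standard errors but drive no decision in the shipped scenarios.

## Predictions P1–P9 and the two strategies

P1/P4/P7 are imputation-specific; P2/P5/P8 average them on the response
scale, P3/P6/P9 average the linear predictors first and then apply `h`.
For identity links the two pooling scales coincide exactly; under a logit
link they differ by a Jensen gap that vanishes when all replicate linear
predictors agree.  Since `h` is monotone, P3/P6/P9 rank individuals exactly
as the pooled linear predictor does, so AUROC is identical on either scale.

P7 pairs secondary-imputation covariates `x^(j)` with primary-fit
coefficients `beta^(k)`.  Because the indices are distinct, the full
`M2 x M` grid of replicate columns is used under imputation-specific
coefficients — the only convention that is well defined when `M2 != M`.  A
`paired` option (j = k, requiring `M2 = M`) exists for sensitivity checks.
When pooling performance over the grid, the `M2·M` cells are treated as a
flat set of replicates; a nested two-way variance decomposition would be a
natural refinement but is not implemented.

Pooled performance applies Rubin's rules to per-replicate measures (MSPE
and calibration slopes pooled untransformed by default; an optional logit
transform is available for AUROC).  Pooled prediction applies the measure
once to averaged predictions; its `PerformanceEstimate` carries no
between-imputation component, which is precisely its weakness — the
averaged predictions are a single deterministic function of the observed
data including the outcomes, and measures computed on them are generally
optimistic.

## Partial prediction models

For every observed-covariate subset present in the data, a reduced model
containing only those covariates is fitted to *all* rows of every primary
imputed dataset, and each individual is scored by the model matching their
own pattern, using observed values only.  A test enforces this by poisoning
masked cells with sentinels and asserting invariance.  Patterns absent from
the derivation data raise a routing error at prediction time rather than
falling back silently, since no principled fallback exists.  Overall
measures pool across all rows regardless of pattern.

## Synthetic trial data

The generator emulates a psychiatric trial with n=708: three skewed
continuous covariates stored on their log scale — baseline symptom score
`cprs0` (log(x+1), mean 2.73, SD 0.82), months since onset `onset` (log,
4.62/0.98), disability `distot` (log, −0.07/0.81) — plus `age` (38.29/11.64
truncated to [18, 65] by rejection on the latent draw), binary `sex`
(404/708) and outpatient `status` (418/708), and a four-level `centre`
(probabilities 196/158/201/153 over 708; the first level is the dummy
reference so published centre coefficients apply).  The real joint
distribution is unpublished, so all variables share an exchangeable
Gaussian copula with one latent correlation (default 0.2), chosen to make
covariates mutually correlated and univariately predictive; quantities that
depend on the covariate joint (e.g. imputation-row table cells) are
therefore comparable only qualitatively, and the test suite checks them as
orderings, not values.

Outcomes are simulated from fixed generating models: a linear model for the
two-year log symptom score (intercept 1.64, `log1p_cprs0` 0.34 — 0.68 in
the strong variant — residual *variance* 0.61) and two logistic models for
dichotomized outcomes at roughly 26.5% and 8.6% prevalence.  Interpreting
the noise term's 0.61 as a variance (not an SD) is corroborated by the
full-data in-sample MSPE: `sigma^2 (n − p)/n × 100 = 60.1` at n=708, p=10,
which the simulations reproduce; an SD interpretation would put it near 37.

The auxiliary `occgp_missing` indicator (a "missing father's occupation"
flag, 132/708 ≈ 19% prevalence) is generated from a fixed logistic model
`logit p = −2.126 + 0.03(age − 38.29) + 0.5·sex + 0.5·status`; the slopes
were chosen to give moderate dependence on all three demographics and the
intercept solved numerically (n = 2·10⁶) for the 19% prevalence.  Only the
indicator matters — it is the stage-model outcome of the MAR mechanism —
so no occupation values are generated.

## Missingness mechanisms

* Independent MCAR deletes exactly `round(rate·n)` rows per variable
  (30% cprs0, 10% onset, 10% distot in the canonical scenarios); exact-`k`
  deletion, with counts rounded half-up, rather than Bernoulli thinning.
* Monotone MCAR uses three disjoint 10% subgroups giving the nested
  pattern distot ⊂ onset ⊂ cprs0.
* Staged MAR fits, at each stage, a logistic model for `occgp_missing` on
  fully observed drivers among not-yet-deleted rows and deletes the top
  fraction of fitted probabilities (fractions 1/10, 1/9, 1/8 for the 30%
  scenario; 1/5, 1/4, 1/3 for 60%), with drivers `{age, sex, status}`
  gaining `distot` at stage 2 and `onset` at stage 3.  `centre` is excluded
  from the stage models so missingness depends more evenly on the other
  covariates.  Ties in fitted probabilities are broken by a seeded jitter.

Outcomes are never masked.

## Chained-equations PMM

Each incomplete variable is imputed by predictive mean matching: a Bayesian
linear regression draw (`sigma*^2` from the scaled inverse-chi-square
posterior, `beta*` from `N(beta_hat, sigma*^2 (X'X)^{-1})` via the Cholesky
factor of `X'X`), predictions `X_obs beta_hat` for donors and
`X_mis beta*` for recipients, and a uniform draw among the `donors`
closest donors.  Donor search uses a sorted window of width `2·donors`
around each recipient's insertion point; at the extreme edges of the donor
distribution a boundary donor can enter the candidate window twice, mildly
favouring the single nearest donor there — an accepted approximation.
Defaults: donor pool 5 (pool size 1 is available to mimic older software
defaults but is noisier), 10 burn-in cycles (no convergence diagnostics are
computed; 10 cycles is conventional for monotone-adjacent patterns like
these), variables visited in order of increasing missingness, initial fill
by random draws from observed values.  Each of the `M` chains receives an
independent spawned sub-seed, so a stack is fully determined by
(mask, config, seed).  Conditional models use all covariate-role variables
(plus the outcome if `include_outcome`); the auxiliary indicator is not
used as an imputation predictor — the MAR drivers themselves are all
included, which preserves MAR validity.  Only continuous variables are
imputable; the shipped mechanisms never delete binary/categorical values.

## Scenario engine

A replicate draws fresh covariates, simulates the outcome, induces
missingness, builds primary and secondary stacks, fits full and partial
models, and evaluates every requested method.  Reference analyses (full
data, complete cases) fit and evaluate their *own* model, so each row of a
result table describes a complete strategy, not a shared fit.  Replicate
failures are redrawn with fresh sub-seeds; more than 5% failures aborts the
scenario.  MSPE is reported ×100.  Default `reps` is 1000; the acceptance
tests run directional checks at 200 replicates, where the key orderings
(P5 < P4 < partial < P8 < P7 for MSPE under 30% MAR; AUROC(P5) > AUROC(P4))
are decisive at alpha = 0.01 in one-sided paired t-tests.  By default each
replicate redraws covariates; `fixed_covariates=True` reuses one covariate
base and redraws only outcomes and missingness, reproducing the conditional
simulation design in which the completed covariate table is held fixed.

## What passing tests do and do not show

The suite verifies the algebraic identities (Rubin arithmetic, unit
calibration slopes on self-derived predictions, identity-link pooling
equalities, Jensen's inequality for pooled-prediction MSPE, AUROC against a
brute-force pair count), the mechanism counts, the PMM donor property, and
the directional simulation findings under the synthetic covariate joint.
It cannot certify numerical table cells that depend on the unpublished
covariate joint of the real trial, nor behaviour under missingness
mechanisms (e.g. MNAR, missing outcomes) and variable types (categorical
imputation) that the package deliberately excludes.
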