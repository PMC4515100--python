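# mipred

Deriving a clinical prediction model is hard enough when every covariate is
recorded; in practice baseline measurements are missing for many patients.
Multiple imputation (MI) is the standard remedy for *fitting* such a model —
but once a model is fitted to `M` imputed datasets, it is surprisingly
unclear how to *use* it: which predictions should be extracted, and how
should performance measures such as the mean squared prediction error
(MSPE/Brier score), the AUROC or the calibration slope be computed from
them?  `mipred` is a library and command-line tool for biostatisticians
studying exactly this question.

## The model and the prediction taxonomy

A GLM prediction model fitted to the *k*-th imputed dataset is

    E[y_i] = h(x_i^(k)' beta^(k)),   k = 1..M,

with `h` the inverse link (identity or expit).  Rubin's rules pool the
coefficients (`beta_bar = mean_k beta^(k)`; total variance
`T = W + (1 + 1/M) B` with within-imputation `W` and between-imputation `B`).
Predictions can then be built from three covariate sources × three pooling
choices, the families **P1–P9**:

| covariates                          | imputation-specific | pooled response | pooled linear predictor |
|-------------------------------------|---------------------|-----------------|-------------------------|
| fully observed rows `x_i`           | P1                  | P2              | P3                      |
| primary imputations `x_i^(k)`       | P4                  | P5              | P6                      |
| secondary imputations `x_i^(j)`     | P7                  | P8              | P9                      |

The *primary* imputations include the outcome among the imputation
predictors (correct for derivation); the *secondary* ones exclude it,
imitating deployment where outcomes are unknown.  Two evaluation strategies
exist: **pooled performance** (compute the measure per replicate, combine by
Rubin's rules) and **pooled prediction** (average predictions first, compute
the measure once).  The package distinguishes *ideal* performance (future
patients have complete covariates; estimated by P4) from *pragmatic*
performance (future patients have missing covariates handled by a declared
strategy; estimated by P7–P9 or by **partial prediction models** — one
reduced model per observed-covariate pattern, predicting from observed
values only).

Because the motivating trial data (the UK700 psychiatric case-management
trial, n=708) are not public, `mipred.datagen` generates synthetic data
matching the published covariate marginals and simulates outcomes from the
published linear and logistic generating models, and `mipred.simulate` runs
the full derive–impute–assess cycle over configurable scenarios (4 outcome
models × MAR/MCAR mechanisms, shipped as 12 canonical YAML configs).

## Worked example

```python
from mipred import (
    GAUSSIAN_IDENTITY, MAR30_STAGES, MiceConfig, apply_staged_mar,
    builtin_model, evaluate_pooled_prediction, fit_per_imputation,
    generate_covariates, impute_chained, pool_on_response_scale,
    pool_performance, predict_per_imputation, simulate_outcome,
)
from mipred.design import FULL_MODEL_TERMS

cov = generate_covariates(n=708, correlation=0.2, seed=1)
data = simulate_outcome(cov, builtin_model("linear"), seed=2)
mdata = apply_staged_mar(data, MAR30_STAGES, seed=3)          # 30% MAR in cprs0

primary = impute_chained(mdata, MiceConfig(m=5, include_outcome=True, seed=4))
secondary = impute_chained(mdata, MiceConfig(m=5, include_outcome=False, seed=5))
coefs = fit_per_imputation(primary, FULL_MODEL_TERMS, GAUSSIAN_IDENTITY)

y = data.df["y"].to_numpy()
p4 = predict_per_imputation(coefs, "primary_stack", stack=primary)
p7 = predict_per_imputation(coefs, "secondary_stack", stack=secondary)
print(f"ideal MSPE (P4, pooled performance):      {100*pool_performance(y, p4, 'mspe').point:.1f}")
print(f"pragmatic MSPE (P7, pooled performance):  {100*pool_performance(y, p7, 'mspe').point:.1f}")
print(f"optimistic MSPE (P5, pooled prediction):  "
      f"{100*evaluate_pooled_prediction(y, pool_on_response_scale(p4), 'mspe').point:.1f}")
```

prints

```
ideal MSPE (P4, pooled performance):      59.3
pragmatic MSPE (P7, pooled performance):  65.0
optimistic MSPE (P5, pooled prediction):  57.4
```

Read: the model's error on complete future covariates is about 0.59 (×100);
if future patients arrive with this study's missingness pattern and are
imputed without outcomes, the realistic error is larger (65.0); averaging
the derivation imputations' predictions before scoring (P5) *understates*
the error (57.4), because between-imputation variability of predictions
built partly from the observed outcomes is averaged away — which is why the
pooled-prediction strategy is not recommended for performance assessment.

The same pipeline is scriptable from the shell via the `mipred` CLI
(`generate`, `ampute`, `impute`, `evaluate`, `simulate --config <yaml>`).

## Out of scope

Optimism correction (bootstrap/cross-validation), derivation/validation
splitting strategies (imputing jointly vs separately, with or without
outcomes in the validation data), Cox models, and joint imputation of
outcome and covariates are documented design territory but not implemented.
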