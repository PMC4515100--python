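"""Scenario engine: repeated simulation of the full derive-impute-assess cycle.

Each replicate of a scenario

1. generates a fresh synthetic covariate base (optionally a fixed base is
   reused across replicates),
2. simulates the outcome from the chosen generating model,
3. induces missing covariates under the chosen mechanism,
4. multiply imputes twice — once with the outcome in the imputation models
   (primary stack) and once without (secondary stack),
5. fits the full prediction model and the per-pattern partial models to the
   primary stack,
6. constructs the requested predictions (P1-P9, partial) and evaluates each
   measure under both the pooled-performance and pooled-prediction
   strategies, alongside full-data and complete-case reference analyses
   (each of which fits and evaluates its own model).

Replicate-level values are retained; summaries report the mean and the
Monte Carlo error (replicate SD / sqrt(reps)).  MSPE values are stored
multiplied by 100, following the usual reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import partial as partial_mod
from .datagen import OUTCOME, builtin_model, generate_covariates, simulate_outcome
from .design import FULL_MODEL_TERMS, build_design
from .exceptions import InvalidArgumentError, ScenarioError
from .mice import MiceConfig, impute_chained
from .missingness import (
    MAR30_STAGES,
    MAR60_STAGES,
    MissingDataset,
    apply_independent_mcar,
    apply_monotone_mcar,
    apply_staged_mar,
)
from .modelfit import BINOMIAL_LOGIT, GAUSSIAN_IDENTITY, fit_per_imputation
from .perform import evaluate_pooled_prediction, pool_performance
from .predict import (
    pool_on_linear_scale,
    pool_on_response_scale,
    predict_per_imputation,
)

__all__ = ["ScenarioConfig", "SimulationResult", "run_scenario", "summarize"]

#: Independent-MCAR deletion rates of the canonical scenarios.
INDEPENDENT_MCAR_RATES = {"cprs0": 0.3, "onset": 0.1, "distot": 0.1}

ALWAYS_OBSERVED = ("age", "sex", "status", "centre")

DEFAULT_METHODS = (
    "full_data",
    "complete_case",
    "P1",
    "P2",
    "P3",
    "P4",
    "P5",
    "P6",
    "P7",
    "P8",
    "P9",
    "partial_P1",
    "partial_P2",
    "partial_P3",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulation scenario."""

    name: str = "scenario"
    model: str = "linear"
    mechanism: str = "monotone_mar30"
    n: int = 708
    reps: int = 1000
    m: int = 5
    m2: int = 5
    correlation: float = 0.2
    iterations: int = 10
    donors: int = 5
    coef_mode: str = "imputation_specific"
    methods: tuple = DEFAULT_METHODS
    measures: tuple = ()  # empty = default by family (mspe; + auroc for logit)
    seed: int = 0
    fixed_covariates: bool = False

    def __post_init__(self):
        if self.reps < 2:
            raise InvalidArgumentError("reps must be >= 2")
        if self.n < 20:
            raise InvalidArgumentError("n must be >= 20")
        if self.m < 1 or self.m2 < 1:
            raise InvalidArgumentError("M and M2 must be >= 1")
        if self.mechanism not in (
            "monotone_mar30",
            "monotone_mar60",
            "monotone_mcar",
            "independent_mcar",
            "none",
        ):
            raise InvalidArgumentError(f"unknown mechanism {self.mechanism!r}")

    def resolved_measures(self) -> tuple:
        if self.measures:
            return tuple(self.measures)
        model = builtin_model(self.model)
        return ("mspe",) if model.link == "identity" else ("mspe", "auroc")


@dataclass
class SimulationResult:
    """Replicate-level raw values plus their Monte Carlo summary table."""

    config: ScenarioConfig
    table: pd.DataFrame  # columns: method, measure, mean, mc_error
    raw: dict = field(default_factory=dict)  # (method, measure) -> np.ndarray


def summarize(values):
    """Mean and Monte Carlo error (SD / sqrt(reps)) of replicate values."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise InvalidArgumentError("need at least two replicate values")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def _induce_missingness(data, mechanism, seed):
    if mechanism == "monotone_mar30":
        return apply_staged_mar(data, MAR30_STAGES, seed)
    if mechanism == "monotone_mar60":
        return apply_staged_mar(data, MAR60_STAGES, seed)
    if mechanism == "monotone_mcar":
        return apply_monotone_mcar(data, seed)
    if mechanism == "independent_mcar":
        return apply_independent_mcar(data, INDEPENDENT_MCAR_RATES, seed)
    # "none": empty mask
    mask = pd.DataFrame(
        np.zeros(data.df.shape, dtype=bool), columns=data.df.columns, index=data.df.index
    )
    return MissingDataset(data, mask)


def _scale(measure, value):
    return value * 100 if measure == "mspe" else value


def _self_fit_measures(data, rows, link, measures):
    """Fit the full model to the given rows and evaluate it there."""
    df = data.df.iloc[rows]
    X = build_design(df, data.specs, FULL_MODEL_TERMS)
    y = np.asarray(df[OUTCOME], float)
    if link.is_identity:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    else:
        import statsmodels.api as sm

        beta = np.asarray(sm.GLM(y, X, family=sm.families.Binomial()).fit().params)
    lp = X @ beta
    resp = link.inverse(lp)
    from .perform import auroc as _auroc, mspe as _mspe

    out = {}
    for meas in measures:
        if meas == "mspe":
            out[meas] = _scale(meas, _mspe(y, resp)[0])
        elif meas == "auroc":
            out[meas] = _auroc(y, resp)[0]
        else:
            raise InvalidArgumentError(f"unsupported reference measure {meas!r}")
    return out


def _run_replicate(config: ScenarioConfig, seeds, base=None):
    link = GAUSSIAN_IDENTITY if builtin_model(config.model).link == "identity" else BINOMIAL_LOGIT
    measures = config.resolved_measures()
    methods = set(config.methods)
    s_cov, s_out, s_mis, s_imp1, s_imp2 = seeds

    cov = base if base is not None else generate_covariates(config.n, config.correlation, s_cov)
    data = simulate_outcome(cov, builtin_model(config.model), s_out)
    mdata = _induce_missingness(data, config.mechanism, s_mis)
    y = np.asarray(data.df[OUTCOME], float)

    values = {}
    if "full_data" in methods:
        res = _self_fit_measures(data, np.arange(data.n), link, measures)
        for meas, v in res.items():
            values[("full_data", meas)] = v
    if "complete_case" in methods:
        rows = np.flatnonzero(mdata.complete_rows())
        res = _self_fit_measures(data, rows, link, measures)
        for meas, v in res.items():
            values[("complete_case", meas)] = v

    primary = impute_chained(
        mdata,
        MiceConfig(config.m, config.iterations, config.donors, True, s_imp1),
    )
    coefs = fit_per_imputation(primary, FULL_MODEL_TERMS, link)

    pred_sets = {}
    if methods & {"P1", "P2", "P3"}:
        pred_sets["P1"] = predict_per_imputation(
            coefs, "observed_complete_cases", mdata=mdata, coef_mode=config.coef_mode
        )
    if methods & {"P4", "P5", "P6"}:
        pred_sets["P4"] = predict_per_imputation(
            coefs, "primary_stack", stack=primary, coef_mode=config.coef_mode
        )
    if methods & {"P7", "P8", "P9"}:
        secondary = impute_chained(
            mdata,
            MiceConfig(config.m2, config.iterations, config.donors, False, s_imp2),
        )
        pred_sets["P7"] = predict_per_imputation(
            coefs, "secondary_stack", stack=secondary, coef_mode=config.coef_mode
        )
    if methods & {"partial_P1", "partial_P2", "partial_P3"}:
        patterns = partial_mod.enumerate_patterns(mdata, ALWAYS_OBSERVED)
        pmodels = partial_mod.fit_pattern_models(primary, patterns, link)
        pred_sets["partial_P1"] = partial_mod.predict_partial(
            pmodels, mdata, coef_mode=config.coef_mode
        )

    pooled_map = {
        "P2": ("P1", pool_on_response_scale),
        "P3": ("P1", pool_on_linear_scale),
        "P5": ("P4", pool_on_response_scale),
        "P6": ("P4", pool_on_linear_scale),
        "P8": ("P7", pool_on_response_scale),
        "P9": ("P7", pool_on_linear_scale),
        "partial_P2": ("partial_P1", pool_on_response_scale),
        "partial_P3": ("partial_P1", pool_on_linear_scale),
    }
    for method in config.methods:
        if method in ("full_data", "complete_case"):
            continue
        if method in pooled_map:
            base_label, pool_fn = pooled_map[method]
            preds = pool_fn(pred_sets[base_label])
            for meas in measures:
                est = evaluate_pooled_prediction(y, preds, meas)
                values[(method, meas)] = _scale(meas, est.point)
        else:
            preds = pred_sets[method]
            for meas in measures:
                est = pool_performance(y, preds, meas)
                values[(method, meas)] = _scale(meas, est.point)
    return values


def run_scenario(config: ScenarioConfig) -> SimulationResult:
    """Run all replicates of a scenario and summarize with Monte Carlo errors.

    A failed replicate is redrawn with a fresh sub-seed; if more than 5% of
    replicates fail, the scenario aborts with :class:`ScenarioError`.
    """
    root = np.random.SeedSequence(config.seed)
    rep_seqs = root.spawn(config.reps)
    spare = root.spawn(1)[0]
    base = None
    if config.fixed_covariates:
        base_seed = root.spawn(1)[0].generate_state(1)[0] % (2**31)
        base = generate_covariates(config.n, config.correlation, int(base_seed))

    raw: dict = {}
    failures = 0
    max_failures = max(1, int(0.05 * config.reps))
    for r in range(config.reps):
        seq = rep_seqs[r]
        while True:
            seeds = [int(s % (2**31)) for s in seq.generate_state(5)]
            try:
                values = _run_replicate(config, seeds, base)
                break
            except Exception:  # noqa: BLE001 - replicate resampled
                failures += 1
                if failures > max_failures:
                    raise ScenarioError(
                        f"more than 5% of replicates failed ({failures})"
                    ) from None
                spare = spare.spawn(1)[0]
                seq = spare
        for key, v in values.items():
            raw.setdefault(key, []).append(v)

    rows = []
    for (method, meas), vals in raw.items():
        mean, mce = summarize(vals)
        rows.append({"method": method, "measure": meas, "mean": mean, "mc_error": mce})
        raw[(method, meas)] = np.asarray(vals)
    table = pd.DataFrame(rows)
    return SimulationResult(config, table, raw)
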