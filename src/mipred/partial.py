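"""Partial prediction models: one model per observed-covariate pattern.

An alternative route to *pragmatic* performance that never touches imputed
covariate values at prediction time.  For every observed-covariate subset
present in the data, a reduced model containing only those covariates is
fitted — to *all* individuals of every imputed dataset, so each reduced model
borrows the full multiply imputed sample.  At prediction time each row is
routed to the model matching its own observed pattern, and its prediction is
computed from observed covariate values only.  Fully observed rows route to
the full model, so their predictions coincide with the full-model P1 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import build_design, terms_for_covariates
from .exceptions import InvalidArgumentError, ProvenanceError, RoutingError
from .mice import ImputedStack
from .missingness import MissingDataset
from .modelfit import CoefficientSet, LinkSpec, fit_per_imputation
from .predict import PredictionSet

__all__ = ["PatternModelSet", "enumerate_patterns", "fit_pattern_models", "predict_partial"]


def _model_covariates(data) -> list[str]:
    return data.covariate_names()


def _row_patterns(mdata: MissingDataset, covariates) -> list[frozenset]:
    mask = mdata.mask[covariates].to_numpy(bool)
    names = np.array(covariates, dtype=object)
    return [frozenset(names[~row]) for row in mask]


def enumerate_patterns(mdata: MissingDataset, always_observed) -> list[frozenset]:
    """Distinct observed-covariate subsets present in the data.

    Each pattern is the frozenset of observed model covariates of at least
    one row and must contain every ``always_observed`` covariate.  Patterns
    are returned sorted by size, largest (the full set, if present) first.
    """
    covariates = _model_covariates(mdata.data)
    always = frozenset(always_observed)
    for v in always:
        if v not in covariates:
            raise InvalidArgumentError(f"{v!r} is not a model covariate")
        if mdata.mask[v].any():
            raise InvalidArgumentError(f"always-observed covariate {v!r} has missing values")
    patterns = sorted(
        set(_row_patterns(mdata, covariates)),
        key=lambda p: (-len(p), tuple(sorted(p))),
    )
    for p in patterns:
        if not always <= p:
            raise InvalidArgumentError(
                f"pattern {sorted(p)} lacks always-observed covariates"
            )
    return patterns


@dataclass
class PatternModelSet:
    """Reduced models keyed by observed-covariate pattern."""

    patterns: list
    models: dict  # frozenset -> CoefficientSet
    link: LinkSpec

    def route(self, pattern: frozenset) -> CoefficientSet:
        try:
            return self.models[pattern]
        except KeyError:
            raise RoutingError(
                f"no partial model for observed pattern {sorted(pattern)}"
            ) from None

    @property
    def m(self) -> int:
        return next(iter(self.models.values())).m


def fit_pattern_models(
    stack: ImputedStack, patterns, link: LinkSpec
) -> PatternModelSet:
    """Fit the full and each partial model to all rows of every imputed dataset.

    Requires the primary (outcome-included) stack.  The full covariate set is
    always fitted even if no row currently exhibits it.
    """
    if stack.provenance != "primary":
        raise ProvenanceError("partial models must be derived from the primary stack")
    specs = stack.datasets[0].specs
    full = frozenset(stack.datasets[0].covariate_names())
    patterns = list(patterns)
    if full not in patterns:
        patterns.insert(0, full)
    models = {}
    for pattern in patterns:
        terms = terms_for_covariates(sorted(pattern), specs)
        models[pattern] = fit_per_imputation(stack, terms, link)
    return PatternModelSet(patterns, models, link)


def predict_partial(
    models: PatternModelSet, mdata: MissingDataset, coef_mode: str = "imputation_specific"
) -> PredictionSet:
    """Route each row to its pattern's model; predict from observed values only.

    Returns P1-family replicate predictions (one column per imputation under
    ``imputation_specific``, a single column under ``pooled``) covering all
    rows.  Masked covariate cells are never read: each pattern's model simply
    has no term for them.
    """
    if coef_mode not in ("imputation_specific", "pooled"):
        raise InvalidArgumentError(f"bad coef_mode {coef_mode!r}")
    covariates = _model_covariates(mdata.data)
    row_patterns = _row_patterns(mdata, covariates)
    n = mdata.n
    n_cols = models.m if coef_mode == "imputation_specific" else 1
    lp = np.empty((n, n_cols))
    groups: dict[frozenset, list[int]] = {}
    for i, p in enumerate(row_patterns):
        groups.setdefault(p, []).append(i)
    for pattern, rows in groups.items():
        coefs = models.route(pattern)
        X = build_design(mdata.data.df.iloc[rows], mdata.data.specs, coefs.terms)
        if coef_mode == "imputation_specific":
            lp[rows] = np.column_stack(
                [X @ coefs.per_imputation[k] for k in range(coefs.m)]
            )
        else:
            lp[rows] = (X @ coefs.pooled)[:, None]
    reps = tuple(range(n_cols)) if coef_mode == "imputation_specific" else ("pooled",)
    return PredictionSet(
        lp=lp,
        response=models.link.inverse(lp),
        label="P1",
        coef_mode=coef_mode,
        subset=np.arange(n),
        link=models.link,
        replicates=reps,
        family="partial",
    )
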