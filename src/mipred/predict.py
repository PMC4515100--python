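"""The taxonomy of predictions obtainable from multiply imputed data.

With imputation-specific coefficients ``beta^(k)`` from a model fitted to
``M`` imputed datasets, three families of *imputation-specific* predictions
exist, distinguished by where the covariates come from:

* **P1** — ``h(x_i beta^(k))`` for individuals with fully observed
  covariates (``M`` replicates per individual);
* **P4** — ``h(x_i^(k) beta^(k))``, pairing each imputed covariate vector
  with its own imputation's coefficients (``M`` replicates, all rows);
* **P7** — ``h(x_i^(j) beta^(k))`` with covariates from a *second*
  imputation procedure that excluded the outcome; the ``(j)`` and ``(k)``
  indices are distinct, so the full ``M2 x M`` grid of replicates applies.

Averaging replicates row-wise on the response scale yields the pooled
predictions P2/P5/P8; averaging linear predictors first and then applying
``h`` yields P3/P6/P9.  For an identity link the two coincide.  Replacing
``beta^(k)`` by the pooled ``beta_bar`` gives the pooled-coefficient
analogues (one replicate per covariate source).

P4 estimates *ideal* performance (covariates complete in deployment); P7
estimates *pragmatic* performance (deployment imputes without outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import build_design
from .exceptions import InvalidArgumentError, ProvenanceError
from .mice import ImputedStack
from .missingness import MissingDataset
from .modelfit import CoefficientSet, LinkSpec

__all__ = [
    "PredictionSet",
    "predict_per_imputation",
    "pool_on_response_scale",
    "pool_on_linear_scale",
]

_POOL_RESPONSE = {"P1": "P2", "P4": "P5", "P7": "P8"}
_POOL_LINEAR = {"P1": "P3", "P4": "P6", "P7": "P9"}
_POOLED_LABELS = {"P2", "P3", "P5", "P6", "P8", "P9"}


@dataclass
class PredictionSet:
    """Per-individual predictions across imputation replicates.

    Both scales are stored: ``lp`` holds linear predictors and ``response``
    holds ``h(lp)`` (after response-scale pooling, ``lp`` is the inverse
    link of the pooled response where defined).  ``subset`` gives the row
    indices of the source dataset covered: complete cases only for P1-P3,
    all rows otherwise.  ``replicates`` labels the columns (``k``, ``j`` or
    ``(j, k)`` pairs).  ``family`` distinguishes full-model predictions from
    partial-model (observed-covariates-only) ones.
    """

    lp: np.ndarray
    response: np.ndarray
    label: str
    coef_mode: str
    subset: np.ndarray
    link: LinkSpec
    replicates: tuple = ()
    family: str = "full"

    @property
    def n_replicates(self) -> int:
        return self.lp.shape[1]

    @property
    def pooled(self) -> bool:
        return self.label in _POOLED_LABELS


def _lp_matrix(coefs: CoefficientSet, X_list, coef_mode):
    """Columns of linear predictors for (design, beta) pairings."""
    if coef_mode == "imputation_specific":
        return np.column_stack([X @ b for X, b in X_list])
    return np.column_stack([X @ coefs.pooled for X, _ in X_list])


def predict_per_imputation(
    coefs: CoefficientSet,
    source: str,
    mdata: MissingDataset | None = None,
    stack: ImputedStack | None = None,
    coef_mode: str = "imputation_specific",
    paired: bool = False,
) -> PredictionSet:
    """Construct P1, P4 or P7 replicate predictions.

    Parameters
    ----------
    source : {"observed_complete_cases", "primary_stack", "secondary_stack"}
        P1 needs ``mdata`` (its complete cases are used); P4/P7 need
        ``stack``.  A secondary stack must have been imputed with the
        outcome excluded, otherwise a :class:`ProvenanceError` is raised.
    coef_mode : {"imputation_specific", "pooled"}
        Pair covariate replicates with their own ``beta^(k)`` or use the
        pooled ``beta_bar`` throughout.
    paired : bool
        For P7 with imputation-specific coefficients, use the diagonal
        ``j = k`` pairing instead of the full ``M2 x M`` grid (requires
        ``M2 = M``).
    """
    if coef_mode not in ("imputation_specific", "pooled"):
        raise InvalidArgumentError(f"bad coef_mode {coef_mode!r}")

    if source == "observed_complete_cases":
        if mdata is None:
            raise InvalidArgumentError("P1 requires the missing dataset")
        rows = np.flatnonzero(mdata.complete_rows())
        X = build_design(mdata.data.df.iloc[rows], mdata.data.specs, coefs.terms)
        if coef_mode == "imputation_specific":
            lp = np.column_stack([X @ coefs.per_imputation[k] for k in range(coefs.m)])
            reps = tuple(range(coefs.m))
        else:
            lp = (X @ coefs.pooled)[:, None]
            reps = ("pooled",)
        label = "P1"
    elif source == "primary_stack":
        if stack is None:
            raise InvalidArgumentError("P4 requires the primary stack")
        rows = np.arange(stack.datasets[0].n)
        Xs = [build_design(ds.df, ds.specs, coefs.terms) for ds in stack.datasets]
        if coef_mode == "imputation_specific":
            if stack.m != coefs.m:
                raise InvalidArgumentError("stack size and coefficient count differ")
            lp = np.column_stack([Xs[k] @ coefs.per_imputation[k] for k in range(stack.m)])
            reps = tuple(range(stack.m))
        else:
            lp = np.column_stack([X @ coefs.pooled for X in Xs])
            reps = tuple(range(stack.m))
        label = "P4"
    elif source == "secondary_stack":
        if stack is None:
            raise InvalidArgumentError("P7 requires the secondary stack")
        if stack.include_outcome or stack.provenance != "secondary":
            raise ProvenanceError(
                "P7 covariates must come from an imputation that excluded the outcome"
            )
        rows = np.arange(stack.datasets[0].n)
        Xs = [build_design(ds.df, ds.specs, coefs.terms) for ds in stack.datasets]
        if coef_mode == "imputation_specific":
            if paired:
                if stack.m != coefs.m:
                    raise InvalidArgumentError("paired P7 requires M2 = M")
                lp = np.column_stack(
                    [Xs[k] @ coefs.per_imputation[k] for k in range(stack.m)]
                )
                reps = tuple((k, k) for k in range(stack.m))
            else:
                cols, reps = [], []
                for j in range(stack.m):
                    for k in range(coefs.m):
                        cols.append(Xs[j] @ coefs.per_imputation[k])
                        reps.append((j, k))
                lp = np.column_stack(cols)
                reps = tuple(reps)
        else:
            lp = np.column_stack([X @ coefs.pooled for X in Xs])
            reps = tuple(range(stack.m))
        label = "P7"
    else:
        raise InvalidArgumentError(f"unknown prediction source {source!r}")

    return PredictionSet(
        lp=lp,
        response=coefs.link.inverse(lp),
        label=label,
        coef_mode=coef_mode,
        subset=rows,
        link=coefs.link,
        replicates=reps,
    )


def _require_replicated(preds: PredictionSet):
    if preds.pooled or preds.n_replicates < 2:
        raise InvalidArgumentError("prediction set is already pooled (single replicate)")


def pool_on_response_scale(preds: PredictionSet) -> PredictionSet:
    """Row-wise mean of response-scale replicates (P1->P2, P4->P5, P7->P8)."""
    _require_replicated(preds)
    mean_resp = preds.response.mean(axis=1, keepdims=True)
    if preds.link.is_identity:
        lp = mean_resp.copy()
    else:
        # keep the linear predictor recoverable without inverting h at 0/1
        eps = np.finfo(float).tiny
        lp = preds.link.link(np.clip(mean_resp, eps, 1 - eps))
    return replace(
        preds,
        lp=lp,
        response=mean_resp,
        label=_POOL_RESPONSE.get(preds.label, preds.label),
        replicates=("pooled_response",),
    )


def pool_on_linear_scale(preds: PredictionSet, link: LinkSpec | None = None) -> PredictionSet:
    """Row-wise mean of linear predictors, then ``h`` (P1->P3, P4->P6, P7->P9)."""
    _require_replicated(preds)
    link = link or preds.link
    mean_lp = preds.lp.mean(axis=1, keepdims=True)
    return replace(
        preds,
        lp=mean_lp,
        response=link.inverse(mean_lp),
        label=_POOL_LINEAR.get(preds.label, preds.label),
        replicates=("pooled_linear",),
    )
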