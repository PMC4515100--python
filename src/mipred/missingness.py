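"""Induce covariate missingness under MCAR and staged-MAR mechanisms.

Three mechanisms mirror a common epidemiological simulation design in which
baseline severity (cprs0), time since onset (onset) and disability (distot)
become missing while demographics stay complete:

* *independent MCAR* — each variable loses an exact, uniformly chosen
  fraction of rows, independently across variables;
* *monotone MCAR* — three disjoint random 10% subgroups produce a nested
  pattern (distot missing => onset missing => cprs0 missing);
* *staged monotone MAR* — the same nested pattern, but driven by fitted
  probabilities from logistic models for an auxiliary "missing father's
  occupation" indicator regressed on fully observed covariates, so that
  missingness depends on observed data.

Outcomes are never made missing: the methods under study all assume fully
observed outcomes in the derivation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datagen import OUTCOME, CompleteDataset
from .exceptions import InvalidArgumentError, StageFitError

__all__ = [
    "MissingDataset",
    "MarStageSpec",
    "apply_independent_mcar",
    "apply_monotone_mcar",
    "apply_staged_mar",
    "MAR30_STAGES",
    "MAR60_STAGES",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class MissingDataset:
    """A complete dataset plus a missingness mask.

    ``data`` retains the true values (so simulations can compare against the
    full data); ``mask`` marks which cells are to be treated as missing.
    ``pattern_id`` identifies each row's observed-covariate subset as a
    comma-joined sorted string of its *missing* covariates ("" = complete).
    """

    data: CompleteDataset
    mask: pd.DataFrame
    pattern_id: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.mask.shape != self.data.df.shape or list(self.mask.columns) != list(
            self.data.df.columns
        ):
            raise InvalidArgumentError("mask dimensions must match data")
        if OUTCOME in self.mask.columns and self.mask[OUTCOME].any():
            raise InvalidArgumentError("outcome column must never be masked")
        missing_cols = self.mask.to_numpy(bool)
        names = np.array(self.mask.columns)
        self.pattern_id = np.array(
            [",".join(sorted(names[row])) for row in missing_cols], dtype=object
        )

    @property
    def n(self) -> int:
        return self.data.n

    def observed_df(self) -> pd.DataFrame:
        """The data with masked cells replaced by NaN (as an analyst sees it)."""
        return self.data.df.mask(self.mask)

    def complete_rows(self) -> np.ndarray:
        """Boolean vector: rows with no missing cell in any column."""
        return ~self.mask.to_numpy(bool).any(axis=1)

    def missing_counts(self) -> pd.Series:
        return self.mask.sum()


def _empty_mask(data: CompleteDataset) -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros(data.df.shape, dtype=bool), columns=data.df.columns, index=data.df.index
    )


def _check_maskable(data: CompleteDataset, variables) -> None:
    for v in variables:
        spec = data.spec(v)
        if spec.role != "covariate":
            raise InvalidArgumentError(f"cannot induce missingness in {spec.role} variable {v!r}")


def apply_independent_mcar(
    data: CompleteDataset, rates: dict, seed: int = 0
) -> MissingDataset:
    """Delete an exact fraction of each listed variable completely at random.

    For each variable, exactly ``round(rate * n)`` rows are masked, chosen
    uniformly without replacement and independently across variables.
    """
    _check_maskable(data, rates)
    for v, r in rates.items():
        if not 0 <= r < 1:
            raise InvalidArgumentError(f"rate for {v!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = _empty_mask(data)
    for v, r in rates.items():
        k = _round_half_up(r * data.n)
        rows = rng.choice(data.n, size=k, replace=False)
        mask.iloc[rows, mask.columns.get_loc(v)] = True
    return MissingDataset(data, mask)


def apply_monotone_mcar(data: CompleteDataset, seed: int = 0) -> MissingDataset:
    """Nested MCAR: three disjoint 10% subgroups.

    distot is deleted in subgroup 1, onset in subgroups 1–2, cprs0 in
    subgroups 1–3, producing a monotone pattern with 30% missing cprs0.
    """
    if data.n < 10:
        raise InvalidArgumentError("monotone MCAR needs n >= 10")
    _check_maskable(data, ["cprs0", "onset", "distot"])
    rng = np.random.default_rng(seed)
    g = _round_half_up(0.1 * data.n)
    perm = rng.permutation(data.n)
    g1, g2, g3 = perm[:g], perm[g : 2 * g], perm[2 * g : 3 * g]
    mask = _empty_mask(data)
    mask.iloc[g1, mask.columns.get_loc("distot")] = True
    mask.iloc[np.concatenate([g1, g2]), mask.columns.get_loc("onset")] = True
    mask.iloc[np.concatenate([g1, g2, g3]), mask.columns.get_loc("cprs0")] = True
    return MissingDataset(data, mask)


@dataclass(frozen=True)
class MarStageSpec:
    """One stage of the staged-MAR mechanism.

    A logistic model for the auxiliary indicator is fitted on ``drivers``
    among rows not deleted at earlier stages; the top ``fraction`` of fitted
    probabilities have ``delete`` masked.
    """

    drivers: tuple
    fraction: float
    delete: tuple

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise InvalidArgumentError("stage fraction must be in (0, 1)")
        if not self.delete:
            raise InvalidArgumentError("stage must delete at least one variable")


#: Stages inducing 30% MAR missingness in cprs0 (10% per stage).
MAR30_STAGES = (
    MarStageSpec(("age", "sex", "status"), 1 / 10, ("cprs0", "onset", "distot")),
    MarStageSpec(("distot", "age", "sex", "status"), 1 / 9, ("cprs0", "onset")),
    MarStageSpec(("onset", "distot", "age", "sex", "status"), 1 / 8, ("cprs0",)),
)

#: Stages inducing 60% MAR missingness in cprs0 (20% per stage).
MAR60_STAGES = (
    MarStageSpec(("age", "sex", "status"), 1 / 5, ("cprs0", "onset", "distot")),
    MarStageSpec(("distot", "age", "sex", "status"), 1 / 4, ("cprs0", "onset")),
    MarStageSpec(("onset", "distot", "age", "sex", "status"), 1 / 3, ("cprs0",)),
)


def apply_staged_mar(
    data: CompleteDataset,
    stages=MAR30_STAGES,
    seed: int = 0,
    indicator: str = "occgp_missing",
) -> MissingDataset:
    """Staged monotone MAR missingness driven by an auxiliary indicator.

    At each stage a logistic regression of ``indicator`` on the stage's
    driver covariates is fitted among individuals untouched by earlier
    stages; the stage's variables are masked for the fraction of remaining
    individuals with the highest fitted probabilities.  Ties in fitted
    probabilities are broken by a seeded random jitter of the rank order.
    """
    if not stages:
        raise InvalidArgumentError("stages must be non-empty")
    if indicator not in data.df.columns:
        raise InvalidArgumentError(f"auxiliary indicator {indicator!r} not in data")
    for st in stages:
        _check_maskable(data, st.delete)
        for d in st.drivers:
            if d not in data.df.columns:
                raise InvalidArgumentError(f"driver variable {d!r} not in data")
    rng = np.random.default_rng(seed)
    mask = _empty_mask(data)
    remaining = np.arange(data.n)
    for st in stages:
        sub = data.df.iloc[remaining]
        X = np.column_stack(
            [np.ones(len(sub))] + [np.asarray(sub[d], dtype=float) for d in st.drivers]
        )
        yv = np.asarray(sub[indicator], dtype=float)
        try:
            res = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageFitError(f"stage logistic fit failed: {exc}") from exc
        if not res.converged:
            raise StageFitError("stage logistic fit did not converge")
        fitted = np.asarray(res.fittedvalues)
        k = _round_half_up(st.fraction * len(remaining))
        jitter = rng.random(len(remaining)) * 1e-12
        order = np.argsort(-(fitted + jitter), kind="stable")
        hit = remaining[order[:k]]
        for v in st.delete:
            mask.iloc[hit, mask.columns.get_loc(v)] = True
        remaining = remaining[order[k:]]
    return MissingDataset(data, mask)
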