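"""Design-matrix construction shared by model fitting, prediction and imputation.

Model terms are named by what enters the linear predictor:

* ``"intercept"`` — a column of ones;
* a raw column name (``"age"``, ``"sex"``) — the stored values;
* ``"<transform>_<name>"`` (``"log1p_cprs0"``, ``"log_onset"``) — a column
  whose :class:`~mipred.datagen.VariableSpec` declares that transform.  Values
  are stored already on the transformed scale, so the term simply resolves to
  the stored column; the prefix documents the modelling scale;
* ``"<categorical><level>"`` (``"centre2"``) — a dummy indicator against the
  first level as reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import MissingTermError

#: Linear-predictor terms of the full seven-covariate prediction model
#: (10 parameters including intercept; centre level 1 is the reference).
FULL_MODEL_TERMS: tuple[str, ...] = (
    "intercept",
    "log1p_cprs0",
    "age",
    "log_onset",
    "log_distot",
    "sex",
    "status",
    "centre2",
    "centre3",
    "centre4",
)


def resolve_term(term: str, df: pd.DataFrame, specs) -> np.ndarray:
    """Return the design column for a single model term as a float vector."""
    if term == "intercept":
        return np.ones(len(df))
    if term in df.columns:
        return np.asarray(df[term], dtype=float)
    for spec in specs:
        if spec.transform != "none" and term == f"{spec.transform}_{spec.name}":
            return np.asarray(df[spec.name], dtype=float)
        if spec.dtype == "categorical" and term.startswith(spec.name):
            level = term[len(spec.name):]
            labels = [str(lab) for lab in spec.levels()]
            if level in labels:
                return (df[spec.name].astype(str) == level).to_numpy(dtype=float)
    raise MissingTermError(f"cannot resolve model term {term!r} from dataset columns")


def build_design(df: pd.DataFrame, specs, terms) -> np.ndarray:
    """Assemble an ``n x p`` design matrix for the given terms."""
    return np.column_stack([resolve_term(t, df, specs) for t in terms])


def terms_for_covariate(name: str, specs) -> list[str]:
    """Model terms contributed by one covariate (dummies for categoricals)."""
    for spec in specs:
        if spec.name == name:
            if spec.dtype == "categorical":
                return [f"{name}{lab}" for lab in spec.levels()[1:]]
            if spec.transform != "none":
                return [f"{spec.transform}_{name}"]
            return [name]
    raise MissingTermError(f"no variable spec named {name!r}")


def terms_for_covariates(names, specs, intercept: bool = True) -> list[str]:
    """Full term list (optionally with intercept) for a covariate subset.

    Order follows ``FULL_MODEL_TERMS`` where applicable so that nested models
    share coefficient ordering with the full model.
    """
    terms = ["intercept"] if intercept else []
    for name in names:
        terms.extend(terms_for_covariate(name, specs))
    # stable re-order against the canonical full-model ordering
    canon = {t: i for i, t in enumerate(FULL_MODEL_TERMS)}
    terms.sort(key=lambda t: canon.get(t, len(canon)))
    return terms
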