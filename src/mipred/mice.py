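"""Multiple imputation by chained equations with predictive mean matching.

The imputer creates ``M`` completed copies of a dataset with missing
covariates.  Each incomplete variable is imputed from a Bayesian linear
regression on all other covariates — and, optionally, the outcome — followed
by donor matching: every missing value receives the *observed* value of one
of the ``donors`` cases whose predicted mean is closest to the recipient's.
Because imputed values are always observed donor values, imputations respect
the support of the data.

Whether the outcome enters the imputation models is the crucial switch here.
Including it (the standard recommendation for model *derivation*) preserves
covariate-outcome associations; excluding it imitates deployment, where a new
patient's outcome is unknown.  Stacks are tagged with this provenance so that
downstream prediction constructions can refuse a stack built the wrong way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

from .datagen import OUTCOME, CompleteDataset
from .design import build_design, terms_for_covariate
from .exceptions import ImputationError, InvalidArgumentError
from .missingness import MissingDataset

__all__ = ["MiceConfig", "ImputedStack", "impute_chained", "pmm_draw"]


@dataclass(frozen=True)
class MiceConfig:
    """Settings for chained-equations imputation.

    Parameters
    ----------
    m : int
        Number of imputed datasets.
    iterations : int
        Full chained-equation cycles per dataset before it is emitted.
    donors : int
        Predictive-mean-matching donor-pool size (1 mimics older software
        defaults; small pools around 5 trade a little bias for less noise).
    include_outcome : bool
        Whether the outcome joins the predictors of every conditional model.
    seed : int
        Master seed; each of the ``m`` chains receives an independent
        spawned sub-seed, so ``m`` and ``seed`` fully determine the stack.
    """

    m: int = 5
    iterations: int = 10
    donors: int = 5
    include_outcome: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.iterations < 1 or self.donors < 1:
            raise InvalidArgumentError("m, iterations and donors must all be >= 1")


@dataclass
class ImputedStack:
    """``m`` completed copies of a partially observed dataset."""

    datasets: list
    include_outcome: bool
    provenance: str  # "primary" (outcome used) or "secondary" (outcome excluded)
    seed: int
    mask: object = None  # original missingness mask (pd.DataFrame)

    def __post_init__(self):
        if not self.datasets:
            raise InvalidArgumentError("stack needs at least one dataset")
        if self.provenance not in ("primary", "secondary"):
            raise InvalidArgumentError(f"bad provenance {self.provenance!r}")

    @property
    def m(self) -> int:
        return len(self.datasets)


def pmm_draw(
    y_obs,
    X_obs,
    X_mis,
    donors: int,
    rng: np.random.Generator,
    bayes: bool = True,
):
    """Impute by predictive mean matching for one variable.

    Fits ``y_obs ~ X_obs`` by least squares, draws ``sigma*^2`` from the
    scaled inverse-chi-square posterior and ``beta*`` from
    ``N(beta_hat, sigma*^2 (X'X)^-1)`` (suppressed when ``bayes=False``, in
    which case ``beta* = beta_hat``).  Donor cases are ranked by
    ``X_obs @ beta_hat``; each recipient, ranked by ``X_mis @ beta*``,
    receives the observed value of one of its ``donors`` nearest donors,
    chosen uniformly.
    """
    y_obs = np.asarray(y_obs, float)
    X_obs = np.asarray(X_obs, float)
    X_mis = np.asarray(X_mis, float)
    n, p = X_obs.shape
    if len(y_obs) != n or n < p + 1:
        raise InvalidArgumentError("need rows(y_obs) = rows(X_obs) >= columns + 1")
    if donors > n:
        raise InvalidArgumentError("donor pool larger than number of observed cases")

    beta_hat, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    if rank < p:
        warnings.warn(
            "collinear columns in imputation design; proceeding with minimum-norm fit",
            stacklevel=2,
        )
    resid = y_obs - X_obs @ beta_hat
    if bayes and rank == p:
        ssr = float(resid @ resid)
        df = n - p
        sigma2 = ssr / rng.chisquare(df) if ssr > 0 else 0.0
        c, low = cho_factor(X_obs.T @ X_obs)
        # upper Cholesky R of X'X: solve R w = z gives w ~ N(0, (X'X)^-1)
        z = rng.standard_normal(p)
        beta_star = beta_hat + np.sqrt(sigma2) * solve_triangular(c, z, lower=low)
    else:
        beta_star = beta_hat

    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    offsets = np.arange(-donors, donors)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    nearest = np.argpartition(dist, donors - 1, axis=1)[:, :donors]
    pick = rng.integers(0, donors, size=len(pred_mis))
    chosen = cand[np.arange(len(pred_mis)), nearest[np.arange(len(pred_mis)), pick]]
    return y_obs[order[chosen]]


def _predictor_terms(data: CompleteDataset, target: str, include_outcome: bool):
    terms = ["intercept"]
    for spec in data.specs:
        if spec.role != "covariate" or spec.name == target or spec.name not in data.df:
            continue
        terms.extend(terms_for_covariate(spec.name, data.specs))
    if include_outcome and OUTCOME in data.df:
        terms.append(OUTCOME)
    return terms


def impute_chained(mdata: MissingDataset, config: MiceConfig) -> ImputedStack:
    """Run chained-equations PMM and return the stack of completed datasets.

    Incomplete variables are visited in order of increasing missingness; the
    initial fill draws uniformly from each variable's observed values; each
    chain runs ``config.iterations`` full cycles before its dataset is
    emitted.  Observed cells are never altered.
    """
    mask = mdata.mask
    miss_counts = mask.sum()
    targets = [c for c in mask.columns if miss_counts[c] > 0]
    targets.sort(key=lambda c: miss_counts[c])
    provenance = "primary" if config.include_outcome else "secondary"
    if not targets:
        return ImputedStack(
            [mdata.data.copy() for _ in range(config.m)],
            config.include_outcome,
            provenance,
            config.seed,
            mask,
        )
    if config.include_outcome and OUTCOME not in mdata.data.df:
        raise InvalidArgumentError("include_outcome=True but dataset has no outcome column")
    for c in targets:
        if (~mask[c]).sum() == 0:
            raise ImputationError(f"variable {c!r} has no observed donors")
        if mdata.data.spec(c).dtype != "continuous":
            raise ImputationError(f"only continuous variables can be imputed ({c!r})")

    children = np.random.SeedSequence(config.seed).spawn(config.m)
    datasets = []
    for k in range(config.m):
        rng = np.random.default_rng(children[k])
        comp = mdata.data.copy()
        df = comp.df
        # initial fill: random draws from observed values
        for c in targets:
            mis = mask[c].to_numpy()
            obs_vals = df.loc[~mis, c].to_numpy()
            df.loc[mis, c] = rng.choice(obs_vals, size=mis.sum(), replace=True)
        for _ in range(config.iterations):
            for c in targets:
                mis = mask[c].to_numpy()
                terms = _predictor_terms(comp, c, config.include_outcome)
                X = build_design(df, comp.specs, terms)
                imputed = pmm_draw(
                    df.loc[~mis, c].to_numpy(),
                    X[~mis],
                    X[mis],
                    config.donors,
                    rng,
                )
                df.loc[mis, c] = imputed
        datasets.append(comp)
    return ImputedStack(datasets, config.include_outcome, provenance, config.seed, mask)
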