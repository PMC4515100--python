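"""Fit the prediction GLM per imputed dataset and pool by Rubin's rules.

A generalized linear prediction model ``E[y] = h(x'beta)`` is fitted by
maximum likelihood to each of the ``M`` completed datasets, giving
imputation-specific coefficients ``beta^(k)``.  Rubin's rules combine them:

* pooled estimate  ``beta_bar = mean_k beta^(k)``
* within variance  ``W = mean_k Cov(beta^(k))``
* between variance ``B = sample covariance of the beta^(k)``
* total variance   ``T = W + (1 + 1/M) B``

Gaussian-identity models are solved by ordinary least squares with the exact
OLS covariance; binomial-logit models by iteratively reweighted least squares
(statsmodels GLM, max 100 iterations, deviance tolerance 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from .datagen import OUTCOME
from .design import build_design
from .exceptions import FitError, InvalidArgumentError
from .mice import ImputedStack

__all__ = [
    "LinkSpec",
    "GAUSSIAN_IDENTITY",
    "BINOMIAL_LOGIT",
    "CoefficientSet",
    "fit_per_imputation",
    "pool_coefficients",
    "rubin_df",
]


@dataclass(frozen=True)
class LinkSpec:
    """GLM family with its inverse link ``h``."""

    family: str  # "gaussian-identity" or "binomial-logit"

    def __post_init__(self):
        if self.family not in ("gaussian-identity", "binomial-logit"):
            raise InvalidArgumentError(f"unsupported family {self.family!r}")

    @property
    def is_identity(self) -> bool:
        return self.family == "gaussian-identity"

    def inverse(self, lp):
        """Apply ``h`` (identity or expit) to a linear predictor."""
        return np.asarray(lp, float) if self.is_identity else expit(lp)

    def link(self, mu):
        """Apply ``h^{-1}`` (identity or logit) to response-scale values."""
        if self.is_identity:
            return np.asarray(mu, float)
        mu = np.asarray(mu, float)
        if np.any((mu <= 0) | (mu >= 1)):
            raise InvalidArgumentError("cannot invert logit at probabilities 0 or 1")
        return logit(mu)


GAUSSIAN_IDENTITY = LinkSpec("gaussian-identity")
BINOMIAL_LOGIT = LinkSpec("binomial-logit")


@dataclass
class CoefficientSet:
    """Per-imputation and Rubin-pooled GLM coefficients.

    ``per_imputation`` is ``(M, p)``; ``covariances`` is ``(M, p, p)``;
    ``within``/``between``/``total`` are the ``(p, p)`` Rubin components.
    """

    terms: tuple
    per_imputation: np.ndarray
    covariances: np.ndarray
    pooled: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray
    link: LinkSpec
    df: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.per_imputation.shape[0]

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Coefficient vector of imputation ``k`` (``None`` = pooled)."""
        return self.pooled if k is None else self.per_imputation[k]


def pool_coefficients(estimates):
    """Apply Rubin's rules to ``[(vector, covariance), ...]``.

    Returns ``(pooled, W, B, T)``.  ``B`` uses denominator ``M - 1`` and is a
    zero matrix when ``M = 1``.
    """
    if not estimates:
        raise InvalidArgumentError("need at least one estimate")
    p = len(np.asarray(estimates[0][0]))
    for b, v in estimates:
        if len(np.asarray(b)) != p or np.asarray(v).shape != (p, p):
            raise InvalidArgumentError("estimate lengths/covariances do not match")
    betas = np.asarray([np.asarray(b, float) for b, _ in estimates])
    covs = np.asarray([np.asarray(v, float) for _, v in estimates])
    m = len(estimates)
    pooled = betas.mean(axis=0)
    within = covs.mean(axis=0)
    if m > 1:
        dev = betas - pooled
        between = dev.T @ dev / (m - 1)
    else:
        between = np.zeros((p, p))
    total = within + (1 + 1 / m) * between
    return pooled, within, between, total


def rubin_df(within: np.ndarray, between: np.ndarray, m: int) -> np.ndarray:
    """Per-term Rubin (1987) degrees of freedom; infinite where B = 0."""
    w = np.diag(within)
    b = np.diag(between)
    with np.errstate(divide="ignore"):
        r = (1 + 1 / m) * b
        out = np.where(b > 0, (m - 1) * (1 + w / np.where(r > 0, r, 1)) ** 2, np.inf)
    return out


def _fit_gaussian(X, y):
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError(f"rank-deficient design (rank {rank} < {p} columns)")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p) if n > p else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2 * xtx_inv


def _fit_binomial(X, y):
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError("outcome has a single class; logistic fit undefined")
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise FitError("IRLS did not converge")
    return np.asarray(res.params), np.asarray(res.cov_params())


def fit_per_imputation(
    stack: ImputedStack, terms, link: LinkSpec, outcome: str = OUTCOME
) -> CoefficientSet:
    """Fit the model with the given terms to every dataset of the stack."""
    terms = tuple(terms)
    estimates = []
    for k, ds in enumerate(stack.datasets):
        X = build_design(ds.df, ds.specs, terms)
        y = np.asarray(ds.df[outcome], float)
        try:
            if link.is_identity:
                estimates.append(_fit_gaussian(X, y))
            else:
                estimates.append(_fit_binomial(X, y))
        except FitError as exc:
            raise FitError(f"imputation {k}: {exc}") from exc
    pooled, within, between, total = pool_coefficients(estimates)
    return CoefficientSet(
        terms=terms,
        per_imputation=np.asarray([b for b, _ in estimates]),
        covariances=np.asarray([v for _, v in estimates]),
        pooled=pooled,
        within=within,
        between=between,
        total=total,
        link=link,
        df=rubin_df(within, between, len(estimates)),
    )


def coefficients_to_dict(coefs: CoefficientSet) -> dict:
    """JSON-serializable summary of a coefficient set."""
    return {
        "terms": list(coefs.terms),
        "family": coefs.link.family,
        "per_imputation": coefs.per_imputation.tolist(),
        "pooled": coefs.pooled.tolist(),
        "within_diag": np.diag(coefs.within).tolist(),
        "between_diag": np.diag(coefs.between).tolist(),
        "total_diag": np.diag(coefs.total).tolist(),
    }
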