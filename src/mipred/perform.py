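"""Performance measures and the two pooling strategies.

Two routes lead from replicate predictions to one performance number:

* **pooled performance** — compute the measure (and its sampling variance)
  once per imputation replicate, then combine with Rubin's rules:
  point = mean, total variance ``T = W + (1 + 1/M) B``;
* **pooled prediction** — average the predictions first (P2/P3/P5/P6/P8/P9)
  and compute the measure once on the averaged predictions.

The pooled-prediction route looks attractive but is generally optimistic:
averaging removes the between-imputation variability of predictions built
partly from the observed outcome, so squared errors shrink by convexity.

Measures
--------
``mspe``
    Mean squared prediction error; with binary outcomes and predicted
    probabilities this is the Brier score.
``auroc``
    Mann-Whitney concordance (ties get half credit) with the
    Hanley-McNeil variance.
``calibration_slope``
    Slope from regressing observed outcomes on predictions: ordinary least
    squares on the response scale for identity links, logistic regression on
    the linear predictor for logit links.  A well-calibrated model has
    slope 1; predictions evaluated on the very data that estimated them give
    slope 1 exactly by least-squares algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

from .exceptions import (
    DegenerateOutcomeError,
    InvalidArgumentError,
    UndefinedSlopeError,
)
from .modelfit import GAUSSIAN_IDENTITY, LinkSpec
from .predict import PredictionSet

__all__ = [
    "PerformanceEstimate",
    "mspe",
    "auroc",
    "calibration_slope",
    "pool_performance",
    "evaluate_pooled_prediction",
]


@dataclass
class PerformanceEstimate:
    """A performance measure with Rubin variance components.

    ``within`` is the mean sampling variance (W), ``between`` the
    between-replicate variance (B, absent for the pooled-prediction
    strategy), ``total`` is ``W + (1 + 1/M) B``.
    """

    measure: str
    point: float
    within: float
    between: float | None
    total: float
    m: int
    strategy: str  # "pooled_performance", "pooled_prediction" or "single"
    transform: str = "none"

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def mspe(y, pred):
    """Mean squared prediction error and its sampling variance.

    Returns ``(estimate, variance)`` where the variance is the sample
    variance of the squared errors divided by ``n``.
    """
    y = np.asarray(y, float)
    pred = np.asarray(pred, float)
    if y.size == 0 or y.shape != pred.shape:
        raise InvalidArgumentError("y and pred must be equal-length and non-empty")
    sq = (y - pred) ** 2
    est = float(sq.mean())
    var = float(sq.var(ddof=1) / len(sq)) if len(sq) > 1 else 0.0
    return est, var


def auroc(y, score):
    """Mann-Whitney AUROC and Hanley-McNeil variance.

    Concordance of (case, non-case) pairs with half credit for ties; equals
    ``(sum of case ranks - n1(n1+1)/2) / (n1 n0)`` with midranks.
    """
    y = np.asarray(y)
    score = np.asarray(score, float)
    if y.shape != score.shape or y.size == 0:
        raise InvalidArgumentError("y and score must be equal-length and non-empty")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateOutcomeError("AUROC needs both outcome classes")
    ranks = rankdata(score)
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    return float(a), float(max(var, 0.0))


def calibration_slope(y, pred, link: LinkSpec = GAUSSIAN_IDENTITY):
    """Calibration slope and its standard error.

    For an identity link, ``pred`` must be response-scale predictions and the
    slope comes from OLS of ``y`` on ``pred``.  For a logit link, ``pred``
    must be the *linear predictor* and the slope comes from logistic
    regression of ``y`` on it.
    """
    y = np.asarray(y, float)
    pred = np.asarray(pred, float)
    if y.shape != pred.shape or y.size < 3:
        raise InvalidArgumentError("need equal-length y and pred with n >= 3")
    if np.ptp(pred) == 0:
        raise UndefinedSlopeError("calibration slope undefined for constant predictions")
    X = np.column_stack([np.ones_like(pred), pred])
    if link.is_identity:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (len(y) - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return float(beta[1]), float(np.sqrt(cov[1, 1]))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    return float(res.params[1]), float(res.bse[1])


def _replicate_measure(measure, y, preds: PredictionSet, col: int):
    if measure == "mspe":
        return mspe(y, preds.response[:, col])
    if measure == "auroc":
        return auroc(y, preds.response[:, col])
    if measure == "calibration_slope":
        if preds.link.is_identity:
            est, se = calibration_slope(y, preds.response[:, col], preds.link)
        else:
            est, se = calibration_slope(y, preds.lp[:, col], preds.link)
        return est, se**2
    raise InvalidArgumentError(f"unknown measure {measure!r}")


def pool_performance(
    y, preds: PredictionSet, measure: str, transform: str = "none"
) -> PerformanceEstimate:
    """Rubin's rules over imputation-specific performance estimates.

    ``y`` is the full outcome vector; the rows covered by ``preds.subset``
    are used.  With ``transform="logit"`` (sensible for AUROC) pooling is
    done on the logit scale and the point estimate is back-transformed.
    """
    if preds.pooled:
        raise InvalidArgumentError("pooled-performance strategy needs replicate predictions")
    if transform not in ("none", "logit"):
        raise InvalidArgumentError(f"unsupported transform {transform!r}")
    y_sub = np.asarray(y, float)[preds.subset]
    ests, variances = [], []
    for col in range(preds.n_replicates):
        try:
            est, var = _replicate_measure(measure, y_sub, preds, col)
        except Exception as exc:  # noqa: BLE001 - name the failing replicate
            raise type(exc)(f"replicate {preds.replicates[col]}: {exc}") from exc
        if transform == "logit":
            deriv = est * (1 - est)
            if deriv <= 0:
                raise InvalidArgumentError("logit transform undefined at estimate 0 or 1")
            var = var / deriv**2
            est = float(logit(est))
        ests.append(est)
        variances.append(var)
    m = len(ests)
    point = float(np.mean(ests))
    within = float(np.mean(variances))
    between = float(np.var(ests, ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    if transform == "logit":
        point = float(expit(point))
    return PerformanceEstimate(
        measure, point, within, between, total, m, "pooled_performance", transform
    )


def evaluate_pooled_prediction(y, pooled: PredictionSet, measure: str) -> PerformanceEstimate:
    """Compute a measure directly on pooled (single-replicate) predictions."""
    if pooled.n_replicates != 1:
        raise InvalidArgumentError("pooled-prediction strategy needs a single replicate")
    y_sub = np.asarray(y, float)[pooled.subset]
    est, var = _replicate_measure(measure, y_sub, pooled, 0)
    return PerformanceEstimate(
        measure, float(est), float(var), None, float(var), 1, "pooled_prediction"
    )
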