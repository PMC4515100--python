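"""Synthetic generation of UK700-like psychiatric-trial data.

The UK700 case-management trial enrolled 708 adults aged 18–65 with psychotic
illness across four inner-city UK centres.  Symptom severity was measured with
the Comprehensive Psychopathological Rating Scale (CPRS) at baseline and two
years.  This module generates covariate data whose marginal distributions
match the published trial summaries, and simulates continuous or binary
outcomes from the published generating models, so that simulation studies of
missing-data strategies can run without access to the (non-public) trial data.

Skewed scales (baseline CPRS, time since onset of psychosis, total disability)
are handled on their log scale throughout: generated values are stored already
log-transformed, and variable specs record which transform the stored scale
corresponds to.  The joint covariate distribution of the real trial is
unknown; a Gaussian copula with a single exchangeable latent correlation
(default 0.2) couples all covariates, giving mutually correlated and
univariately predictive covariates with one tunable knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import build_design
from .exceptions import InvalidArgumentError, MissingTermError

__all__ = [
    "VariableSpec",
    "CompleteDataset",
    "GeneratingModel",
    "generate_covariates",
    "builtin_model",
    "simulate_outcome",
    "OUTCOME",
]

#: Name of the simulated outcome column.
OUTCOME = "y"


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one dataset variable.

    Parameters
    ----------
    name : str
        Column name.
    role : {"outcome", "covariate", "auxiliary"}
    dtype : {"continuous", "binary", "categorical"}
    transform : {"none", "log", "log1p"}
        Modelling-scale transform.  Stored column values are *already* on the
        transformed scale; the label records which transform that is.
    mean, sd : float, optional
        Marginal mean and SD on the transformed scale (continuous variables).
    probs : dict, optional
        Category label -> probability (binary/categorical variables).
    """

    name: str
    role: str
    dtype: str
    transform: str = "none"
    mean: float | None = None
    sd: float | None = None
    probs: dict | None = None

    def __post_init__(self):
        if self.role not in ("outcome", "covariate", "auxiliary"):
            raise InvalidArgumentError(f"bad role {self.role!r}")
        if self.dtype not in ("continuous", "binary", "categorical"):
            raise InvalidArgumentError(f"bad dtype {self.dtype!r}")
        if self.transform not in ("none", "log", "log1p"):
            raise InvalidArgumentError(f"bad transform {self.transform!r}")
        if self.transform == "log1p" and self.dtype != "continuous":
            raise InvalidArgumentError("log1p transform requires a continuous variable")
        if self.sd is not None and not self.sd > 0:
            raise InvalidArgumentError("SD must be positive")
        if self.probs is not None:
            total = sum(self.probs.values())
            if abs(total - 1.0) > 1e-12:
                raise InvalidArgumentError(
                    f"category probabilities for {self.name!r} sum to {total}, not 1"
                )

    def levels(self) -> list:
        """Category labels in declaration order (first = reference)."""
        if self.probs is None:
            raise InvalidArgumentError(f"{self.name!r} has no categories")
        return list(self.probs)


@dataclass
class CompleteDataset:
    """A rectangular dataset with no missing entries plus variable metadata."""

    df: pd.DataFrame
    specs: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self):
        named = {s.name for s in self.specs}
        for col in self.df.columns:
            if col not in named:
                raise InvalidArgumentError(f"column {col!r} has no VariableSpec")
        if self.df.isna().any().any():
            raise InvalidArgumentError("CompleteDataset must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.df)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise MissingTermError(f"no variable spec named {name!r}")

    def covariate_names(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "covariate" and s.name in self.df]

    def copy(self) -> "CompleteDataset":
        return CompleteDataset(self.df.copy(), list(self.specs))


@dataclass(frozen=True)
class GeneratingModel:
    """A known linear or logistic outcome model used to simulate data.

    ``link="identity"`` adds Gaussian noise with variance ``noise_variance``;
    ``link="logit"`` draws Bernoulli outcomes from the expit of the linear
    predictor.  Coefficient keys are model terms in the sense of
    :mod:`mipred.design`.
    """

    link: str
    coefficients: dict
    noise_variance: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.link not in ("identity", "logit"):
            raise InvalidArgumentError(f"bad link {self.link!r}")
        if "intercept" not in self.coefficients:
            raise InvalidArgumentError("coefficient map must include an intercept")
        if self.link == "identity" and not (self.noise_variance and self.noise_variance > 0):
            raise InvalidArgumentError("identity link requires noise variance > 0")
        if self.link == "logit" and self.noise_variance is not None:
            raise InvalidArgumentError("logit link has no noise term")


# --- published trial summaries -------------------------------------------
# Continuous covariates on their modelling (log) scale: mean, SD.
_CONTINUOUS = {
    "cprs0": ("log1p", 2.73, 0.82),   # log(baseline CPRS + 1)
    "onset": ("log", 4.62, 0.98),     # log months since onset of psychosis
    "distot": ("log", -0.07, 0.81),   # log total disability score
}
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 38.29, 11.64, 18.0, 65.0
_P_SEX = 404 / 708          # male
_P_STATUS = 418 / 708       # outpatient at recruitment
_CENTRE_COUNTS = (196, 158, 201, 153)   # St George's, Manchester, St Mary's, King's

# Logistic model driving the missing-father's-occupation indicator
# (~19% prevalence; drivers age, sex, status; intercept solved numerically
# for 132/708 prevalence under the default copula).
_OCCGP_COEFS = {"intercept": -2.126, "age_centred": 0.03, "sex": 0.5, "status": 0.5}

_LINEAR_COEFS = {
    "intercept": 1.64,
    "log1p_cprs0": 0.34,
    "age": -0.01,
    "log_onset": 0.11,
    "log_distot": 0.20,
    "sex": -0.19,
    "status": 0.15,
    "centre2": 0.06,
    "centre3": 0.30,
    "centre4": 0.0008,
}
_LOGISTIC_25_COEFS = {
    "intercept": -3.20,
    "log1p_cprs0": 0.75,
    "age": -0.03,
    "log_onset": 0.25,
    "log_distot": 0.44,
    "sex": -0.28,
    "status": -0.14,
    "centre2": -0.29,
    "centre3": 0.91,
    "centre4": 0.16,
}
_LOGISTIC_8_COEFS = {
    "intercept": -6.54,
    "log1p_cprs0": 1.13,
    "age": -0.04,
    "log_onset": 0.37,
    "log_distot": 0.51,
    "sex": -0.50,
    "status": -0.07,
    "centre2": -0.63,
    "centre3": 1.55,
    "centre4": 0.86,
}


def builtin_model(name: str) -> GeneratingModel:
    """Return one of the four built-in outcome-generating models.

    ``linear`` is the published two-year log-CPRS model with residual
    variance 0.61; ``linear_strong`` doubles the baseline-CPRS coefficient
    (0.34 -> 0.68).  ``logistic_25`` / ``logistic_8`` generate dichotomized
    CPRS outcomes with roughly 26.5% and 8.6% prevalence.
    """
    if name == "linear":
        return GeneratingModel("identity", dict(_LINEAR_COEFS), 0.61, "linear")
    if name == "linear_strong":
        coefs = dict(_LINEAR_COEFS)
        coefs["log1p_cprs0"] = 0.68
        return GeneratingModel("identity", coefs, 0.61, "linear_strong")
    if name == "logistic_25":
        return GeneratingModel("logit", dict(_LOGISTIC_25_COEFS), None, "logistic_25")
    if name == "logistic_8":
        return GeneratingModel("logit", dict(_LOGISTIC_8_COEFS), None, "logistic_8")
    raise InvalidArgumentError(f"unknown builtin model {name!r}")


def covariate_specs() -> list[VariableSpec]:
    """Variable specs for the generated covariate catalogue."""
    specs = []
    for name, (transform, mean, sd) in _CONTINUOUS.items():
        specs.append(VariableSpec(name, "covariate", "continuous", transform, mean, sd))
    specs.append(VariableSpec("age", "covariate", "continuous", "none", _AGE_MEAN, _AGE_SD))
    specs.append(VariableSpec("sex", "covariate", "binary", probs={0: 1 - _P_SEX, 1: _P_SEX}))
    specs.append(
        VariableSpec("status", "covariate", "binary", probs={0: 1 - _P_STATUS, 1: _P_STATUS})
    )
    total = sum(_CENTRE_COUNTS)
    specs.append(
        VariableSpec(
            "centre",
            "covariate",
            "categorical",
            probs={i + 1: c / total for i, c in enumerate(_CENTRE_COUNTS)},
        )
    )
    p_occ = 132 / 708
    specs.append(
        VariableSpec("occgp_missing", "auxiliary", "binary", probs={0: 1 - p_occ, 1: p_occ})
    )
    return specs


def generate_covariates(n: int, correlation: float = 0.2, seed: int = 0) -> CompleteDataset:
    """Generate ``n`` synthetic covariate rows.

    All covariates share an exchangeable Gaussian copula with latent
    correlation ``correlation``.  Continuous variables are generated directly
    on their transformed (log) scale with the published means and SDs; age is
    truncated to [18, 65] by rejection; binary/categorical variables threshold
    their latent normal at the published frequencies.  The auxiliary
    ``occgp_missing`` indicator (missing father's occupation, ~19% prevalence)
    is drawn from a fixed logistic model in age, sex and status and later
    serves as the outcome of MAR missingness-stage models.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not 0 <= correlation < 1:
        raise InvalidArgumentError("correlation must be in [0, 1)")
    rng = np.random.default_rng(seed)

    names = ["cprs0", "onset", "distot", "age", "sex", "status", "centre"]
    shared = rng.standard_normal(n)
    indep = rng.standard_normal((n, len(names)))
    z = np.sqrt(correlation) * shared[:, None] + np.sqrt(1 - correlation) * indep
    cols = {}
    for i, (name, (_, mean, sd)) in enumerate(_CONTINUOUS.items()):
        cols[name] = mean + sd * z[:, i]

    # age: rejection on the independent latent component keeps the copula
    # coupling while truncating the marginal to the trial's 18-65 range
    zi = z[:, 3].copy()
    age = _AGE_MEAN + _AGE_SD * zi
    bad = (age < _AGE_LO) | (age > _AGE_HI)
    while bad.any():
        zi[bad] = np.sqrt(correlation) * shared[bad] + np.sqrt(1 - correlation) * (
            rng.standard_normal(bad.sum())
        )
        age = _AGE_MEAN + _AGE_SD * zi
        bad = (age < _AGE_LO) | (age > _AGE_HI)
    cols["age"] = age

    from scipy.stats import norm

    u_sex = norm.cdf(z[:, 4])
    cols["sex"] = (u_sex < _P_SEX).astype(int)
    u_status = norm.cdf(z[:, 5])
    cols["status"] = (u_status < _P_STATUS).astype(int)
    total = sum(_CENTRE_COUNTS)
    cum = np.cumsum([c / total for c in _CENTRE_COUNTS])
    cols["centre"] = 1 + np.searchsorted(cum, norm.cdf(z[:, 6]), side="right").clip(0, 3)

    lp = (
        _OCCGP_COEFS["intercept"]
        + _OCCGP_COEFS["age_centred"] * (cols["age"] - _AGE_MEAN)
        + _OCCGP_COEFS["sex"] * cols["sex"]
        + _OCCGP_COEFS["status"] * cols["status"]
    )
    cols["occgp_missing"] = (rng.random(n) < expit(lp)).astype(int)

    df = pd.DataFrame(cols)
    return CompleteDataset(df, covariate_specs())


def simulate_outcome(
    data: CompleteDataset, model: GeneratingModel, seed: int = 0
) -> CompleteDataset:
    """Append a simulated outcome column ``y`` drawn from ``model``.

    Identity link: ``y = x'beta + N(0, noise_variance)``.  Logit link:
    ``y ~ Bernoulli(expit(x'beta))``.
    """
    rng = np.random.default_rng(seed)
    terms = list(model.coefficients)
    X = build_design(data.df, data.specs, terms)
    lp = X @ np.array([model.coefficients[t] for t in terms])
    df = data.df.copy()
    if model.link == "identity":
        df[OUTCOME] = lp + rng.normal(0.0, np.sqrt(model.noise_variance), data.n)
        spec = VariableSpec(OUTCOME, "outcome", "continuous", "log1p")
    else:
        df[OUTCOME] = (rng.random(data.n) < expit(lp)).astype(int)
        spec = VariableSpec(OUTCOME, "outcome", "binary")
    return CompleteDataset(df, list(data.specs) + [spec])


def linear_predictor(data: CompleteDataset, model: GeneratingModel) -> np.ndarray:
    """Evaluate a generating model's linear predictor on a dataset."""
    terms = list(model.coefficients)
    X = build_design(data.df, data.specs, terms)
    return X @ np.array([model.coefficients[t] for t in terms])
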