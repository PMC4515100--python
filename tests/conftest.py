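"""Shared fixtures: one small synthetic trial dataset and its imputations."""

import numpy as np
import pytest

from mipred import (
    GAUSSIAN_IDENTITY,
    MAR30_STAGES,
    MiceConfig,
    apply_staged_mar,
    builtin_model,
    fit_per_imputation,
    generate_covariates,
    impute_chained,
    simulate_outcome,
)
from mipred.design import FULL_MODEL_TERMS


@pytest.fixture(scope="session")
def linear_data():
    """n=708 covariates with a continuous outcome from the linear model."""
    cov = generate_covariates(708, 0.2, seed=101)
    return simulate_outcome(cov, builtin_model("linear"), seed=102)


@pytest.fixture(scope="session")
def mar30(linear_data):
    """Monotone MAR missingness (30% cprs0) on the linear dataset."""
    return apply_staged_mar(linear_data, MAR30_STAGES, seed=103)


@pytest.fixture(scope="session")
def primary_stack(mar30):
    """M=5 imputations including the outcome."""
    return impute_chained(mar30, MiceConfig(m=5, include_outcome=True, seed=104))


@pytest.fixture(scope="session")
def secondary_stack(mar30):
    """M2=5 imputations excluding the outcome."""
    return impute_chained(mar30, MiceConfig(m=5, include_outcome=False, seed=105))


@pytest.fixture(scope="session")
def full_coefs(primary_stack):
    return fit_per_imputation(primary_stack, FULL_MODEL_TERMS, GAUSSIAN_IDENTITY)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
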