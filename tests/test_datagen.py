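"""Synthetic covariate generation and outcome simulation."""

import numpy as np
import pandas as pd
import pytest

from mipred import (
    CompleteDataset,
    GeneratingModel,
    VariableSpec,
    builtin_model,
    generate_covariates,
    simulate_outcome,
)
from mipred.datagen import linear_predictor
from mipred.exceptions import InvalidArgumentError, MissingTermError


class TestGenerateCovariates:
    def test_marginals_match_trial_summaries(self):
        # published transformed-scale marginals, n=1e5, tolerance 0.02
        data = generate_covariates(100_000, 0.2, seed=1)
        df = data.df
        for name, mean, sd in [("cprs0", 2.73, 0.82), ("onset", 4.62, 0.98),
                               ("distot", -0.07, 0.81)]:
            assert df[name].mean() == pytest.approx(mean, abs=0.02)
            assert df[name].std() == pytest.approx(sd, abs=0.02)
        assert df["sex"].mean() == pytest.approx(404 / 708, abs=0.01)
        assert df["status"].mean() == pytest.approx(418 / 708, abs=0.01)
        freqs = df["centre"].value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freqs, np.array([196, 158, 201, 153]) / 708, atol=0.01)
        assert df["occgp_missing"].mean() == pytest.approx(132 / 708, abs=0.01)

    def test_age_truncated_to_trial_range(self):
        df = generate_covariates(5000, 0.3, seed=2).df
        assert df["age"].min() >= 18
        assert df["age"].max() <= 65

    def test_same_seed_reproduces_dataset(self):
        a = generate_covariates(50, 0.2, seed=9)
        b = generate_covariates(50, 0.2, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_correlation_knob_couples_covariates(self):
        strong = generate_covariates(20_000, 0.6, seed=3).df
        weak = generate_covariates(20_000, 0.0, seed=3).df
        assert strong["cprs0"].corr(strong["onset"]) > 0.4
        assert abs(weak["cprs0"].corr(weak["onset"])) < 0.05

    @pytest.mark.parametrize("n,corr", [(0, 0.2), (10, 1.0), (10, -0.1)])
    def test_invalid_arguments_rejected(self, n, corr):
        with pytest.raises(InvalidArgumentError):
            generate_covariates(n, corr, seed=0)


class TestBuiltinModels:
    def test_published_coefficients(self):
        linear = builtin_model("linear")
        assert linear.coefficients["intercept"] == 1.64
        assert linear.coefficients["log1p_cprs0"] == 0.34
        assert linear.noise_variance == 0.61
        assert builtin_model("linear_strong").coefficients["log1p_cprs0"] == 0.68
        assert builtin_model("logistic_25").coefficients["log1p_cprs0"] == 0.75
        assert builtin_model("logistic_8").coefficients["intercept"] == -6.54
        assert builtin_model("logistic_8").coefficients["log1p_cprs0"] == 1.13

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            builtin_model("cox")


def _zero_covariate_dataset(n=1):
    cols = {
        "cprs0": np.zeros(n), "onset": np.zeros(n), "distot": np.zeros(n),
        "age": np.zeros(n), "sex": np.zeros(n, dtype=int),
        "status": np.zeros(n, dtype=int), "centre": np.ones(n, dtype=int),
    }
    specs = [
        VariableSpec("cprs0", "covariate", "continuous", "log1p", 0.0, 1.0),
        VariableSpec("onset", "covariate", "continuous", "log", 0.0, 1.0),
        VariableSpec("distot", "covariate", "continuous", "log", 0.0, 1.0),
        VariableSpec("age", "covariate", "continuous"),
        VariableSpec("sex", "covariate", "binary", probs={0: 0.5, 1: 0.5}),
        VariableSpec("status", "covariate", "binary", probs={0: 0.5, 1: 0.5}),
        VariableSpec("centre", "covariate", "categorical",
                     probs={1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}),
    ]
    return CompleteDataset(pd.DataFrame(cols), specs)


class TestSimulateOutcome:
    def test_noiseless_intercept_only(self):
        data = _zero_covariate_dataset()
        model = GeneratingModel("identity", builtin_model("linear").coefficients, 1e-30)
        out = simulate_outcome(data, model, seed=0)
        assert out.df["y"].iloc[0] == pytest.approx(1.64, abs=1e-10)

    def test_logit_symmetry_at_zero_linear_predictor(self):
        n = 40_000
        data = _zero_covariate_dataset(n)
        model = GeneratingModel("logit", {"intercept": 0.0})
        out = simulate_outcome(data, model, seed=4)
        se = 0.5 / np.sqrt(n)
        assert out.df["y"].mean() == pytest.approx(0.5, abs=3 * se)

    def test_noise_variance_recovered(self):
        cov = generate_covariates(100_000, 0.2, seed=5)
        model = builtin_model("linear")
        out = simulate_outcome(cov, model, seed=6)
        noise = out.df["y"].to_numpy() - linear_predictor(cov, model)
        assert np.var(noise, ddof=1) == pytest.approx(0.61, rel=0.02)

    def test_same_seed_bit_reproducible(self, linear_data):
        cov = CompleteDataset(linear_data.df.drop(columns="y"),
                              [s for s in linear_data.specs if s.name != "y"])
        a = simulate_outcome(cov, builtin_model("linear"), seed=7)
        b = simulate_outcome(cov, builtin_model("linear"), seed=7)
        np.testing.assert_array_equal(a.df["y"], b.df["y"])

    def test_unresolvable_term_names_the_term(self):
        data = _zero_covariate_dataset()
        model = GeneratingModel("identity", {"intercept": 1.0, "bmi": 2.0}, 1.0)
        with pytest.raises(MissingTermError, match="bmi"):
            simulate_outcome(data, model, seed=0)


class TestVariableSpec:
    def test_probability_sum_enforced(self):
        with pytest.raises(InvalidArgumentError):
            VariableSpec("x", "covariate", "binary", probs={0: 0.6, 1: 0.5})

    def test_log1p_only_for_continuous(self):
        with pytest.raises(InvalidArgumentError):
            VariableSpec("x", "covariate", "binary", transform="log1p",
                         probs={0: 0.5, 1: 0.5})
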