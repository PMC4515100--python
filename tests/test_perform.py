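"""Performance measures and pooling strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipred import (
    BINOMIAL_LOGIT,
    GAUSSIAN_IDENTITY,
    auroc,
    calibration_slope,
    evaluate_pooled_prediction,
    mspe,
    pool_on_response_scale,
    pool_performance,
    predict_per_imputation,
)
from mipred.exceptions import (
    DegenerateOutcomeError,
    InvalidArgumentError,
    UndefinedSlopeError,
)
from mipred.predict import PredictionSet


def _predset(lp, link=GAUSSIAN_IDENTITY, label="P4"):
    lp = np.asarray(lp, float)
    return PredictionSet(
        lp=lp, response=link.inverse(lp), label=label,
        coef_mode="imputation_specific", subset=np.arange(lp.shape[0]),
        link=link, replicates=tuple(range(lp.shape[1])),
    )


class TestMspe:
    @pytest.mark.parametrize(
        "y,pred,expected",
        [([1, 0], [0.5, 0.5], 0.25), ([0, 2], [1, 1], 1.0), ([3, 1, 4], [3, 1, 4], 0.0)],
    )
    def test_hand_examples(self, y, pred, expected):
        assert mspe(np.array(y, float), np.array(pred, float))[0] == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mspe(np.array([]), np.array([]))


class TestAuroc:
    def test_pair_count_example(self):
        # 4 case/non-case pairs, 3 concordant
        a, _ = auroc(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.4, 0.2]))
        assert a == pytest.approx(0.75)

    def test_perfect_and_constant_scores(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(y, np.array([0.1, 0.2, 0.8, 0.9]))[0] == 1.0
        assert auroc(y, np.ones(4))[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            auroc(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_agrees_with_pairwise_oracle(self, data):
        n = data.draw(st.integers(4, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0], y[1] = 0, 1
        score = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        a, _ = auroc(y, score)
        pos, neg = score[y == 1], score[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert a == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        lp = rng.normal(size=100)
        assert auroc(y, lp)[0] == pytest.approx(auroc(y, 1 / (1 + np.exp(-lp)))[0])


class TestCalibrationSlope:
    def test_fitted_values_give_unit_slope(self, rng):
        x = rng.normal(size=80)
        y = 1 + 2 * x + rng.normal(size=80)
        X = np.column_stack([np.ones(80), x])
        fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        slope, se = calibration_slope(y, fitted)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert se > 0

    def test_closed_form_two_point_slope(self):
        slope, _ = calibration_slope(
            np.array([0.0, 2.0, 0.0, 2.0]), np.array([1.0, 2.0, 1.0, 2.0])
        )
        assert slope == pytest.approx(2.0)

    def test_perfect_predictions_have_unit_slope(self, rng):
        y = rng.normal(size=30)
        assert calibration_slope(y, y)[0] == pytest.approx(1.0)

    def test_constant_predictions_rejected(self):
        with pytest.raises(UndefinedSlopeError):
            calibration_slope(np.arange(5.0), np.ones(5))

    def test_logit_link_recovers_unit_slope_on_true_lp(self, rng):
        n = 5000
        lp = rng.normal(scale=1.5, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        slope, se = calibration_slope(y, lp, BINOMIAL_LOGIT)
        assert slope == pytest.approx(1.0, abs=4 * se)


class TestPoolingStrategies:
    def test_rubin_pooling_of_replicate_measures(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        lp = y[:, None] + rng.normal(size=(50, 5))
        preds = _predset(lp)
        est = pool_performance(y, preds, "mspe")
        per_rep = [mspe(y, lp[:, k]) for k in range(5)]
        ests = [e for e, _ in per_rep]
        variances = [v for _, v in per_rep]
        assert est.point == pytest.approx(np.mean(ests))
        assert est.within == pytest.approx(np.mean(variances))
        assert est.between == pytest.approx(np.var(ests, ddof=1))
        assert est.total == pytest.approx(np.mean(variances) + 1.2 * np.var(ests, ddof=1))
        assert est.strategy == "pooled_performance"

    def test_identical_replicates_have_zero_between_variance(self):
        y = np.arange(10.0)
        preds = _predset(np.tile(np.arange(10.0)[:, None] + 0.5, (1, 4)))
        assert pool_performance(y, preds, "mspe").between == pytest.approx(0.0)

    def test_logit_transform_backtransforms_point(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        lp = rng.normal(size=(200, 3)) + y[:, None]
        preds = _predset(lp, link=BINOMIAL_LOGIT)
        plain = pool_performance(y, preds, "auroc")
        trans = pool_performance(y, preds, "auroc", transform="logit")
        assert 0 < trans.point < 1
        assert trans.point == pytest.approx(plain.point, abs=0.02)

    def test_pooled_prediction_strategy_has_no_between_component(self):
        y = np.arange(12.0)
        pooled = pool_on_response_scale(_predset(np.tile(y[:, None], (1, 3)) + 0.1))
        est = evaluate_pooled_prediction(y, pooled, "mspe")
        assert est.between is None and est.strategy == "pooled_prediction"
        with pytest.raises(InvalidArgumentError):
            evaluate_pooled_prediction(y, _predset(np.ones((12, 3))), "mspe")

    def test_degenerate_single_imputation_strategies_coincide(self):
        import dataclasses

        y = np.arange(15.0)
        single = _predset((y * 0.9 + 0.3)[:, None])
        as_pooled = dataclasses.replace(single, label="P5")
        a = pool_performance(y, single, "mspe")
        b = evaluate_pooled_prediction(y, as_pooled, "mspe")
        assert a.point == pytest.approx(b.point, abs=1e-15)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 10**6))
    def test_mspe_convexity_of_pooled_predictions(self, seed):
        # averaging predictions can only shrink squared error (Jensen)
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 30), rng.integers(2, 6)
        y = rng.normal(size=n)
        preds = _predset(rng.normal(size=(n, m)))
        pooled = pool_on_response_scale(preds)
        lhs = mspe(y, pooled.response[:, 0])[0]
        rhs = np.mean([mspe(y, preds.response[:, k])[0] for k in range(m)])
        assert lhs <= rhs + 1e-12


def test_pooled_prediction_slope_optimistic_for_imputed_rows(
    linear_data, mar30, primary_stack, full_coefs
):
    """Regressing outcomes on averaged predictions overstates calibration for
    rows whose covariates were imputed using the outcome, relative to the
    Rubin-pooled imputation-specific slopes."""
    y = linear_data.df["y"].to_numpy()
    p4 = predict_per_imputation(full_coefs, "primary_stack", stack=primary_stack)
    imputed_rows = np.flatnonzero(~mar30.complete_rows())
    slopes = [
        calibration_slope(y[imputed_rows], p4.response[imputed_rows, k])[0]
        for k in range(p4.n_replicates)
    ]
    pooled_preds = pool_on_response_scale(p4)
    pooled_slope = calibration_slope(
        y[imputed_rows], pooled_preds.response[imputed_rows, 0]
    )[0]
    assert pooled_slope > np.mean(slopes)
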