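"""Diagnostic logistic model, AUC machinery, model card."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulefuse.diagnostic import (
    DiagnosticModel,
    auc_score,
    delong_ci,
    evaluate,
    export_model_card,
    fit_logistic,
    linear_predictor,
    load_model_card,
    predict_proba,
)


def pairwise_auc(scores, labels):
    """O(n^2) oracle: mean over positive-negative pairs of
    [score_p > score_n] + 0.5 [tie]."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFitLogistic:
    def test_all_zero_column_zero_padded(self):
        ind = pd.DataFrame({"dead": [0, 0, 0, 0, 0, 0]})
        y = np.array([1, 0, 1, 0, 0, 0])
        m = fit_logistic(ind, y)
        assert m.coefficients["dead"] == 0.0
        prev = y.mean()
        assert m.intercept == pytest.approx(np.log(prev / (1 - prev)))

    def test_noise_rule_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        ind = pd.DataFrame({"noise": rng.integers(0, 2, n)})
        y = rng.integers(0, 2, n)
        m = fit_logistic(ind, y)
        assert abs(m.coefficients["noise"]) < 0.15

    def test_deterministic_refit(self):
        rng = np.random.default_rng(1)
        ind = pd.DataFrame({"a": rng.integers(0, 2, 100), "b": rng.integers(0, 2, 100)})
        y = (ind["a"].to_numpy() | rng.integers(0, 2, 100)).astype(int)
        m1, m2 = fit_logistic(ind, y), fit_logistic(ind, y)
        for k in m1.coefficients:
            assert m1.coefficients[k] == pytest.approx(m2.coefficients[k], abs=1e-8)

    def test_separation_falls_back_to_ridge(self):
        ind = pd.DataFrame({"perfect": [1, 1, 1, 0, 0, 0]})
        y = np.array([1, 1, 1, 0, 0, 0])
        m = fit_logistic(ind, y)
        assert m.diagnostics["ridge_fallback"]
        assert m.coefficients["perfect"] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"a": [0, 1]}), np.array([1, 1]))


class TestLinearPredictor:
    def test_all_zero_gives_intercept(self, pub_model, zero_indicators):
        Y = linear_predictor(pub_model, zero_indicators)
        assert np.allclose(Y, -0.3265)

    @pytest.mark.parametrize(
        "rule,coef",
        [("Rule1", -0.7705), ("Rule2", -0.4823), ("Rule10", 0.5978),
         ("Rule15", 0.3891)],
    )
    def test_single_rule_delta(self, pub_model, zero_indicators, rule, coef):
        ind = zero_indicators.copy()
        ind[rule] = 1
        delta = linear_predictor(pub_model, ind) - (-0.3265)
        assert np.allclose(delta, coef)

    def test_missing_rule_column_raises(self, pub_model):
        with pytest.raises(KeyError):
            linear_predictor(pub_model, pd.DataFrame({"Rule1": [1]}))

    def test_probability_monotone_in_Y(self, pub_model, zero_indicators):
        ind = zero_indicators.copy()
        p0 = predict_proba(pub_model, ind)
        ind["Rule10"] = 1  # positive coefficient
        p1 = predict_proba(pub_model, ind)
        assert (p1 > p0).all()
        assert ((p0 > 0) & (p0 < 1)).all()


class TestAUC:
    def test_perfect_and_inverted_ordering(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert auc_score([0.9, 0.8, 0.2, 0.1], y) == 0.0

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(10, 60)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # many ties
            assert auc_score(scores, y) == pytest.approx(
                pairwise_auc(scores, y), abs=1e-12
            )

    def test_delong_ci_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(3)
        def ci_width(n):
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = y + rng.normal(0, 0.8, n)
            auc, (lo, hi) = delong_ci(s, y)
            assert lo <= auc <= hi
            return hi - lo
        assert ci_width(800) < ci_width(60)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_auc_pairwise_property(seed):
    """Rank-statistic AUC equals pair enumeration on random tables."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 100))
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    scores = np.round(rng.normal(size=n), 1)
    assert auc_score(scores, y) == pytest.approx(pairwise_auc(scores, y), abs=1e-12)


class TestEvaluate:
    def make(self, seed=4, n=120):
        rng = np.random.default_rng(seed)
        ind = pd.DataFrame({"r": rng.integers(0, 2, n)})
        y = np.where(rng.random(n) < 0.75, ind["r"], 1 - ind["r"]).astype(int)
        model = fit_logistic(ind, y)
        return model, ind, y

    def test_report_fields_consistent(self):
        model, ind, y = self.make()
        rep = evaluate(model, ind, y)
        c = rep.confusion
        assert c["tp"] + c["fp"] + c["tn"] + c["fn"] == len(y)
        assert rep.accuracy == pytest.approx((c["tp"] + c["tn"]) / len(y))
        assert 0 <= rep.auc <= 1
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        # ROC points monotone in fpr
        assert (np.diff(rep.roc_points["fpr"]) >= 0).all()

    def test_bootstrap_ci_close_to_delong(self):
        model, ind, y = self.make(seed=5, n=400)
        d = evaluate(model, ind, y, ci_method="delong")
        b = evaluate(model, ind, y, ci_method="bootstrap", seed=0)
        assert d.auc == pytest.approx(b.auc)
        assert d.auc_ci[0] == pytest.approx(b.auc_ci[0], abs=0.07)

    def test_youden_threshold_used(self):
        model, ind, y = self.make(seed=6)
        rep = evaluate(model, ind, y, youden=True)
        assert rep.threshold != 0.5

    def test_single_class_rejected(self):
        model, ind, _ = self.make()
        with pytest.raises(ValueError):
            evaluate(model, ind, np.ones(len(ind), dtype=int))


class TestModelCard:
    def test_published_card_contains_equation(self, pub_model):
        card = export_model_card(pub_model)
        assert "-0.3265" in card
        assert "Rule15" in card

    def test_round_trip_exact(self, pub_model):
        again = load_model_card(export_model_card(pub_model))
        assert again.intercept == pub_model.intercept
        assert again.coefficients == pub_model.coefficients
        assert [r.signature() for r in again.ruleset] == [
            r.signature() for r in pub_model.ruleset
        ]

    def test_intercept_only_card(self):
        m = DiagnosticModel(intercept=0.7, coefficients={})
        card = export_model_card(m)
        again = load_model_card(card)
        assert again.intercept == 0.7 and again.coefficients == {}
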