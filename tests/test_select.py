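"""Fusion cascade stages: filters, merge, SHAP screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rulefuse.rulefit import SparseLinearModel
from rulefuse.rules import RuleSet, parse_rule, rules_to_dataset
from rulefuse.select import (
    importance_filter,
    lasso_select_rules,
    linear_shap,
    merge_rule_datasets,
    outcome_correlation_filter,
    phi_coefficient,
    shap_filter,
)


def model_with_importances(imps):
    supports = {r: 0.5 for r in imps}
    # choose alpha so that |alpha| * sqrt(.25) = requested importance
    weights = {r: v / 0.5 for r, v in imps.items()}
    return SparseLinearModel(
        intercept=0.0, rule_weights=weights, linear_weights={},
        lam=0.1, supports=supports, column_sds={},
    )


class TestImportanceFilter:
    def test_strictly_exceeding_threshold(self):
        rs = RuleSet([parse_rule("x > 0", id=r) for r in ("a", "b", "c")])
        m = model_with_importances({"a": 0.0, "b": 0.1, "c": 0.3})
        trace = importance_filter(rs, m, thr=0.1)
        assert trace.rules_out == ["c"]  # 0.1 exactly is dropped


class TestCorrelationFilter:
    def test_phi_of_identical_and_complement(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        ind = pd.DataFrame({"same": y, "opp": 1 - y})
        trace = outcome_correlation_filter(ind, y, thr=0.4)
        assert set(trace.rules_out) == {"same", "opp"}
        assert trace.statistic["same"] == pytest.approx(1.0)
        assert trace.statistic["opp"] == pytest.approx(-1.0)

    def test_known_contingency_value(self):
        # 2x2 table (a,b,c,d) = (30,20,20,30): phi = 0.2
        r = np.array([1] * 50 + [0] * 50)
        y = np.array([1] * 30 + [0] * 20 + [1] * 20 + [0] * 30)
        assert phi_coefficient(r, y) == pytest.approx(0.2)
        trace = outcome_correlation_filter(pd.DataFrame({"r": r}), y, thr=0.4)
        assert trace.rules_out == []

    def test_constant_indicator_is_zero(self):
        y = np.array([0, 1, 0, 1])
        trace = outcome_correlation_filter(
            pd.DataFrame({"c": [1, 1, 1, 1]}), y, thr=0.4
        )
        assert trace.statistic["c"] == 0.0


class TestMerge:
    def table(self):
        return pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [5.0, 6.0, 7.0]})

    def ds(self, specs):
        rs = RuleSet([parse_rule(t, id=i, source=s) for i, t, s in specs])
        return rs, rules_to_dataset(rs, self.table())

    def test_distinct_rules_concatenate(self):
        a = self.ds([("a1", "x <= 1", "gbdt"), ("a2", "x > 1", "gbdt")])
        b = self.ds([("b1", "y <= 6", "ada")])
        rules, ind = merge_rule_datasets(a, b)
        assert len(rules) == 3 and list(ind.columns) == ["a1", "a2", "b1"]

    def test_shared_rule_collapses_with_provenance_union(self):
        a = self.ds([("a1", "x <= 1", "gbdt"), ("a2", "x > 1", "gbdt")])
        b = self.ds([("b1", "x <= 1", "rf"), ("b2", "y <= 6", "rf")])
        rules, ind = merge_rule_datasets(a, b)
        assert len(rules) == 3
        shared = rules["a1"]
        assert shared.sources == ("gradient_boosting", "random_forest")

    def test_merge_with_empty_is_identity(self):
        a = self.ds([("a1", "x <= 1", "gbdt")])
        rules, ind = merge_rule_datasets(a, (RuleSet([]), pd.DataFrame()))
        assert rules.ids == ["a1"]

    def test_sample_mismatch_rejected(self):
        a = self.ds([("a1", "x <= 1", "gbdt")])
        rs, ind = self.ds([("b1", "y <= 6", "ada")])
        ind = ind.iloc[:2]
        with pytest.raises(ValueError):
            merge_rule_datasets(a, (rs, ind))


class TestLassoSelect:
    def test_perfect_rule_survives_noise(self):
        rng = np.random.default_rng(0)
        n = 300
        y = rng.integers(0, 2, n).astype(float)
        ind = pd.DataFrame(
            {f"noise{i}": rng.integers(0, 2, n) for i in range(10)}
        )
        ind["signal"] = y
        trace = lasso_select_rules(ind, y, seed=0)
        assert "signal" in trace.rules_out
        # pure-noise rules rarely survive
        assert len(trace.rules_out) <= 4

    def test_forced_large_lambda_selects_nothing(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100).astype(float)
        ind = pd.DataFrame({"a": rng.integers(0, 2, 100)})
        from rulefuse._glm import l1_logistic_path_cv

        path = l1_logistic_path_cv(
            ind.to_numpy(dtype=float), y, lambdas=np.array([50.0, 10.0]), seed=0
        )
        assert (path.coefs == 0).all()


def brute_force_shapley(weights, means, x):
    """Permutation Shapley for a linear model with mean baseline."""
    names = list(weights)
    phi = dict.fromkeys(names, 0.0)
    def value(subset):
        return sum(
            weights[n] * (x[n] if n in subset else means[n]) for n in names
        )
    perms = list(itertools.permutations(names))
    for perm in perms:
        seen = set()
        for n in perm:
            phi[n] += value(seen | {n}) - value(seen)
            seen.add(n)
    return {n: v / len(perms) for n, v in phi.items()}


class TestLinearShap:
    def test_matches_exact_permutation_shapley(self):
        rng = np.random.default_rng(2)
        n, k = 40, 5
        ind = pd.DataFrame(
            {f"r{i}": rng.integers(0, 2, n).astype(float) for i in range(k)}
        )
        weights = {f"r{i}": float(rng.normal()) for i in range(k)}
        phi = linear_shap(weights, ind)
        means = {c: ind[c].mean() for c in ind.columns}
        for i in [0, 7, 23]:
            x = {c: ind[c].iloc[i] for c in ind.columns}
            exact = brute_force_shapley(weights, means, x)
            for c in ind.columns:
                assert phi[c].iloc[i] == pytest.approx(exact[c], abs=1e-10)

    def test_additivity(self):
        rng = np.random.default_rng(3)
        ind = pd.DataFrame(
            {f"r{i}": rng.integers(0, 2, 100).astype(float) for i in range(6)}
        )
        weights = {c: float(rng.normal()) for c in ind.columns}
        phi = linear_shap(weights, ind)
        f = sum(weights[c] * ind[c] for c in ind.columns)
        np.testing.assert_allclose(
            phi.sum(axis=1), f - f.mean(), atol=1e-8
        )


class TestShapFilter:
    def test_zero_weight_and_constant_dropped(self):
        ind = pd.DataFrame(
            {"z": [1, 0, 1, 0], "const": [1, 1, 1, 1], "s": [1, 1, 0, 0]}
        )
        trace = shap_filter(
            {"z": 0.0, "const": 5.0, "s": 2.0}, ind, thr=0.5, mode="raw"
        )
        assert trace.rules_out == ["s"]
        assert trace.statistic["z"] == 0.0
        assert trace.statistic["const"] == 0.0

    def test_normalized_mode_is_scale_free(self):
        ind = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 1, 1, 0]})
        t1 = shap_filter({"a": 1.0, "b": 0.4}, ind, mode="normalized")
        t2 = shap_filter({"a": 100.0, "b": 40.0}, ind, mode="normalized")
        assert t1.rules_out == t2.rules_out

    def test_auto_is_union_of_readings(self):
        ind = pd.DataFrame({"a": [1, 0] * 10, "b": [1, 1, 1, 0] * 5})
        w = {"a": 0.3, "b": 0.2}  # raw contributions all below 0.5
        raw = shap_filter(w, ind, thr=0.5, mode="raw")
        norm = shap_filter(w, ind, thr=0.5, mode="normalized")
        auto = shap_filter(w, ind, thr=0.5, mode="auto")
        assert set(auto.rules_out) == set(raw.rules_out) | set(norm.rules_out)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            shap_filter(object(), pd.DataFrame({"a": [0, 1]}))
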