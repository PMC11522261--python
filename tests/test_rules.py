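"""Rule language: parsing, canonicalization, evaluation, dedup, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulefuse.rules import (
    Condition,
    EmptyRuleError,
    Op,
    Rule,
    RuleParseError,
    RuleSet,
    canonicalize,
    deduplicate,
    evaluate_rule,
    parse_rule,
    prune_conditions,
    read_ruleset,
    rules_to_dataset,
    write_ruleset,
)


class TestParsing:
    def test_bare_flag_name(self):
        r = parse_rule("spiculated margin", id="r")
        assert len(r.conditions) == 1
        c = r.conditions[0]
        assert c.op is Op.FLAG_EQ and c.flag_value == 1
        assert c.feature == "spiculated margin"

    def test_prefixed_rule_records_source(self):
        r = parse_rule(
            "rf_original_glcm_JointEntropy > 8.48 & pleural indentation = 1",
            id="r",
        )
        assert len(r.conditions) == 2
        assert r.sources == ("random_forest",)
        assert all(not c.feature.startswith("rf_") for c in r.conditions)

    def test_thousands_separator_and_unicode_minus(self):
        r = parse_rule(
            "a <  = 45,043.45 & b <  =  −768.75", id="r"
        )
        by_feat = {c.feature: c for c in r.conditions}
        assert by_feat["a"].threshold == 45043.45
        assert by_feat["b"].threshold == -768.75

    def test_interval_left_open_right_closed(self):
        r = parse_rule("m ∈ (122.71,525.63]", id="r")
        c = r.conditions[0]
        assert c.op is Op.INTERVAL and (c.lower, c.upper) == (122.71, 525.63)

    def test_empty_interval_rejected(self):
        with pytest.raises((RuleParseError, EmptyRuleError)):
            parse_rule("x <= 3 & x ∈ (5, 2]", id="r")

    def test_garbage_token_named_in_error(self):
        with pytest.raises(RuleParseError, match="~~"):
            parse_rule("x ~~ 3", id="r")

    def test_all_published_rules_parse(self, pub_rules):
        assert len(pub_rules) == 15
        assert pub_rules["Rule5"].sources == (
            "gradient_boosting",
            "random_forest",
        )

    def test_published_round_trip(self, pub_rules, tmp_path):
        path = tmp_path / "rules.tsv"
        write_ruleset(pub_rules, path)
        again = read_ruleset(path)
        for a, b in zip(pub_rules, again):
            assert a.id == b.id
            assert a.signature() == b.signature()
            assert a.sources == b.sources


class TestCanonicalize:
    def test_le_intersection(self):
        r = Rule("r", (Condition("x", Op.LE, 5.0), Condition("x", Op.LE, 3.0)))
        c = canonicalize(r).conditions
        assert len(c) == 1 and c[0].op is Op.LE and c[0].threshold == 3.0

    def test_interval_formation(self):
        r = Rule("r", (Condition("x", Op.GT, 2.0), Condition("x", Op.LE, 9.0)))
        c = canonicalize(r).conditions[0]
        assert c.op is Op.INTERVAL and (c.lower, c.upper) == (2.0, 9.0)

    def test_contradiction_raises(self):
        r = Rule("r", (Condition("x", Op.GT, 7.0), Condition("x", Op.LE, 3.0)))
        with pytest.raises(EmptyRuleError):
            canonicalize(r)

    def test_conditions_sorted_by_feature(self):
        r = parse_rule("b > 1 & a <= 2", id="r")
        assert [c.feature for c in r.conditions] == ["a", "b"]

    def test_canonical_evaluation_equivalence(self):
        # grid over condition boundaries +/- epsilon
        raw = Rule(
            "r",
            (
                Condition("x", Op.LE, 5.0),
                Condition("x", Op.GT, 1.0),
                Condition("x", Op.LE, 4.0),
            ),
        )
        grid = []
        for b in (1.0, 4.0, 5.0):
            grid += [b - 1e-9, b, b + 1e-9]
        table = pd.DataFrame({"x": grid})
        assert np.array_equal(
            evaluate_rule(raw, table), evaluate_rule(canonicalize(raw), table)
        )


class TestEvaluate:
    RULE1 = (
        "original_shape_MajorAxisLength <  = 12.46 & "
        "original_firstorder_10Percentile <  =  −768.75 & "
        "wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis <  = 45,043.45 & "
        "wavelet-LLH_firstorder_Maximum <  = 487.20"
    )

    def sample(self, **over):
        base = {
            "original_shape_MajorAxisLength": 10.0,
            "original_firstorder_10Percentile": -800.0,
            "wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis": 1000.0,
            "wavelet-LLH_firstorder_Maximum": 400.0,
        }
        base.update(over)
        return pd.DataFrame([base])

    def test_rule1_fires_on_qualifying_sample(self):
        r = parse_rule(self.RULE1, id="Rule1")
        assert evaluate_rule(r, self.sample())[0] == 1

    def test_le_boundary_is_strictly_exceeded(self):
        r = parse_rule(self.RULE1, id="Rule1")
        s = self.sample(original_shape_MajorAxisLength=12.47)
        assert evaluate_rule(r, s)[0] == 0

    def test_interval_excludes_lower_bound(self):
        r = parse_rule("m ∈ (122.71,525.63]", id="r")
        t = pd.DataFrame({"m": [122.71, 122.72, 525.63, 525.64]})
        assert list(evaluate_rule(r, t)) == [0, 1, 1, 0]

    def test_missing_feature_column_raises(self):
        r = parse_rule("zz > 1", id="r")
        with pytest.raises(KeyError):
            evaluate_rule(r, pd.DataFrame({"x": [1.0]}))

    def test_nan_does_not_fire_by_default_and_raises_in_strict(self):
        r = parse_rule("x > 1", id="r")
        t = pd.DataFrame({"x": [2.0, np.nan]})
        assert list(evaluate_rule(r, t)) == [1, 0]
        with pytest.raises(ValueError):
            evaluate_rule(r, t, strict_missing=True)


class TestIndicatorMatrix:
    def test_column_order_and_values(self):
        rs = RuleSet([parse_rule("x <= 1", id="a"), parse_rule("x > 1", id="b")])
        t = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        ind = rules_to_dataset(rs, t)
        assert list(ind.columns) == ["a", "b"]
        # complementary rules partition every sample
        assert (ind.sum(axis=1) == 1).all()

    def test_duplicate_rules_give_identical_columns(self):
        rs = RuleSet([parse_rule("x <= 1", id="a"), parse_rule("x <= 1", id="b")])
        ind = rules_to_dataset(rs, pd.DataFrame({"x": [0.0, 2.0]}))
        assert (ind["a"] == ind["b"]).all()

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError):
            rules_to_dataset(RuleSet([]), pd.DataFrame({"x": [1.0]}))


class TestDeduplicate:
    def test_provenance_union(self):
        rs = RuleSet(
            [
                parse_rule("spiculated margin", id="g", source="gbdt"),
                parse_rule("spiculated margin", id="r", source="rf"),
            ]
        )
        out = deduplicate(rs)
        assert len(out) == 1
        assert out.rules[0].sources == ("gradient_boosting", "random_forest")

    def test_condition_order_irrelevant(self):
        rs = RuleSet(
            [parse_rule("a <= 1 & b > 2", id="x"), parse_rule("b > 2 & a <= 1", id="y")]
        )
        assert len(deduplicate(rs)) == 1

    def test_disjoint_rules_unchanged(self):
        rs = RuleSet([parse_rule("a <= 1", id="x"), parse_rule("b > 2", id="y")])
        assert len(deduplicate(rs)) == 2


class TestPruneConditions:
    def test_nonbinding_condition_removed(self):
        t = pd.DataFrame({"x": np.linspace(0, 1, 100), "y": np.linspace(0, 1, 100)})
        r = parse_rule("x <= 0.5 & y <= 0.99", id="r")
        pruned = prune_conditions(r, t, min_effect=0.05)
        assert [c.feature for c in pruned.conditions] == ["x"]

    def test_binding_conditions_kept(self):
        t = pd.DataFrame({"x": np.linspace(0, 1, 100), "y": np.linspace(1, 0, 100)})
        r = parse_rule("x <= 0.5 & y <= 0.5", id="r")
        assert len(prune_conditions(r, t, min_effect=0.05).conditions) == 2


_FEATURES = st.sampled_from(["alpha", "beta", "gamma delta"])
_THRESH = st.floats(-1e4, 1e4, allow_nan=False).map(lambda v: round(v, 2))


@st.composite
def _random_rule(draw):
    n = draw(st.integers(1, 3))
    conds = []
    for feat in draw(
        st.lists(_FEATURES, min_size=n, max_size=n, unique=True)
    ):
        kind = draw(st.sampled_from(["le", "gt", "interval"]))
        if kind == "interval":
            lo = draw(_THRESH)
            hi = draw(_THRESH.filter(lambda v, lo=lo: v > lo))
            conds.append(Condition(feat, Op.INTERVAL, lower=lo, upper=hi))
        elif kind == "le":
            conds.append(Condition(feat, Op.LE, threshold=draw(_THRESH)))
        else:
            conds.append(Condition(feat, Op.GT, threshold=draw(_THRESH)))
    return canonicalize(Rule("r", tuple(conds)))


@given(_random_rule())
@settings(max_examples=60, deadline=None)
def test_serialize_parse_round_trip(rule):
    """str(rule) re-parses to an identical canonical structure."""
    again = parse_rule(str(rule), id=rule.id)
    assert again.signature() == rule.signature()
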