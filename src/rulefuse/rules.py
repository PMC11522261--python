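"""Conjunctive decision rules over tabular radiomic features.

A *rule* is a conjunction of axis-aligned conditions on named features —
the form produced by walking a root-to-node path in a binary decision
tree.  A rule *fires* on a sample (indicator 1) when every condition
holds.  Boundary semantics follow binary-tree split conventions:
``<=`` is inclusive, ``>`` is strict, and an interval ``(l, u]`` is
left-open, right-closed (equivalent to ``> l`` and ``<= u``).

The textual dialect accepted here is the one used in clinical radiomics
rule tables: ``&``-separated conditions, operators ``<=`` (printed with
arbitrary internal whitespace), ``>``, ``∈ (l, u]``, binary-flag
equality ``= 0/1``, and a bare feature name meaning "flag is set".
Numeric literals may carry thousands separators ("45,043.45") and
Unicode minus signs.  Feature tokens may carry a method prefix
(``gbc_``, ``rf_``, ``ada_``) identifying the ensemble that generated
the rule; prefixes are stripped and recorded as provenance, never kept
in the feature name.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Op",
    "Condition",
    "Rule",
    "RuleSet",
    "RuleParseError",
    "EmptyRuleError",
    "parse_rule",
    "canonicalize",
    "evaluate_rule",
    "rules_to_dataset",
    "deduplicate",
    "read_ruleset",
    "write_ruleset",
]

#: Recognised ensemble-provenance prefixes on feature tokens.
SOURCE_PREFIXES = {
    "gbc_": "gradient_boosting",
    "rf_": "random_forest",
    "ada_": "adaboost",
}

#: Valid values of :attr:`Rule.source`.
SOURCES = (
    "gradient_boosting",
    "random_forest",
    "adaboost",
    "original_feature",
)


class Op(enum.Enum):
    """Condition operator."""

    LE = "<="
    GT = ">"
    INTERVAL = "in"
    FLAG_EQ = "="


class RuleParseError(ValueError):
    """Raised when a rule string cannot be parsed; names the bad token."""


class EmptyRuleError(ValueError):
    """Raised when canonicalization proves a rule logically empty."""


@dataclass(frozen=True)
class Condition:
    """A single threshold, interval, or flag condition on one feature.

    Exactly the fields relevant to ``op`` are set: ``threshold`` for
    LE/GT, ``lower``/``upper`` for INTERVAL (left-open, right-closed),
    ``flag_value`` for FLAG_EQ.
    """

    feature: str
    op: Op
    threshold: float | None = None
    lower: float | None = None
    upper: float | None = None
    flag_value: int | None = None

    def __post_init__(self) -> None:
        if self.op in (Op.LE, Op.GT):
            if self.threshold is None:
                raise ValueError(f"{self.op.name} condition needs a threshold")
        elif self.op is Op.INTERVAL:
            if self.lower is None or self.upper is None:
                raise ValueError("INTERVAL condition needs lower and upper")
            if not self.lower < self.upper:
                raise RuleParseError(
                    f"empty interval ({self.lower}, {self.upper}] on "
                    f"'{self.feature}': lower must be < upper"
                )
        elif self.op is Op.FLAG_EQ:
            if self.flag_value not in (0, 1):
                raise ValueError("FLAG_EQ condition needs flag_value in {0, 1}")

    def holds(self, values: np.ndarray) -> np.ndarray:
        """Vectorized truth of this condition; NaN never satisfies."""
        v = np.asarray(values, dtype=float)
        if self.op is Op.LE:
            return v <= self.threshold
        if self.op is Op.GT:
            return v > self.threshold
        if self.op is Op.INTERVAL:
            return (v > self.lower) & (v <= self.upper)
        return v == self.flag_value

    def __str__(self) -> str:
        if self.op is Op.LE:
            return f"{self.feature} <= {_fmt(self.threshold)}"
        if self.op is Op.GT:
            return f"{self.feature} > {_fmt(self.threshold)}"
        if self.op is Op.INTERVAL:
            return f"{self.feature} ∈ ({_fmt(self.lower)},{_fmt(self.upper)}]"
        return f"{self.feature} = {self.flag_value}"


def _fmt(x: float) -> str:
    """Render a threshold without losing precision or adding noise."""
    return repr(float(x)).rstrip("0").rstrip(".") if "." in repr(float(x)) else repr(float(x))


@dataclass
class Rule:
    """A conjunction of conditions with method provenance.

    ``sources`` lists the rule-generating methods (several after
    deduplication across ensembles).  ``provenance_weight`` carries the
    weight of the generating tree within its ensemble when known.
    """

    id: str
    conditions: tuple[Condition, ...]
    sources: tuple[str, ...] = ("original_feature",)
    provenance_weight: float | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule must have at least one condition")
        for s in self.sources:
            if s not in SOURCES:
                raise ValueError(f"unknown rule source {s!r}")

    @property
    def source(self) -> str:
        """Primary (first) source, for single-provenance rules."""
        return self.sources[0]

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.feature for c in self.conditions))

    def signature(self) -> tuple:
        """Hashable canonical identity: the frozen condition set."""
        return tuple(
            (c.feature, c.op.value, c.threshold, c.lower, c.upper, c.flag_value)
            for c in canonicalize(self).conditions
        )

    def __str__(self) -> str:
        return " & ".join(str(c) for c in self.conditions)


@dataclass
class RuleSet:
    """An ordered collection of uniquely-identified rules."""

    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate rule ids: {dup}")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __getitem__(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rules]

    @property
    def feature_vocabulary(self) -> set[str]:
        return {c.feature for r in self.rules for c in r.conditions}

    def subset(self, ids) -> "RuleSet":
        keep = set(ids)
        return RuleSet([r for r in self.rules if r.id in keep])


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# Numeric literal: optional ASCII/Unicode minus, thousands separators allowed.
_NUM = r"[−\-]?\s*\d{1,3}(?:,\d{3})*(?:\.\d+)?|[−\-]?\s*\d+(?:\.\d+)?"

_RE_INTERVAL = re.compile(
    rf"^(?P<feat>.+?)\s*[∈]\s*\(\s*(?P<lo>{_NUM})\s*,\s*(?P<hi>{_NUM})\s*\]$"
)
_RE_LE = re.compile(rf"^(?P<feat>.+?)\s*<\s*=\s*(?P<thr>{_NUM})\s*$")
_RE_GT = re.compile(rf"^(?P<feat>.+?)\s*>\s*(?P<thr>{_NUM})\s*$")
_RE_FLAG = re.compile(r"^(?P<feat>.+?)\s*=\s*(?P<val>[01])\s*$")
_RE_BARE = re.compile(r"^[A-Za-z_][\w.%\- ]*$")


def _parse_number(tok: str) -> float:
    tok = tok.replace("−", "-").replace(",", "").replace(" ", "")
    return float(tok)


def _strip_prefix(feature: str) -> tuple[str, str | None]:
    for prefix, source in SOURCE_PREFIXES.items():
        if feature.startswith(prefix):
            return feature[len(prefix):], source
    return feature, None


def parse_rule(text: str, id: str, source: str | None = None) -> Rule:
    """Parse one rule string in the table dialect into a canonical Rule.

    Parameters
    ----------
    text:
        ``&``-separated conditions, e.g.
        ``"rf_original_glcm_JointEntropy > 8.48 & pleural indentation = 1"``.
    id:
        Identifier for the resulting rule.
    source:
        Provenance override.  ``"a/b"`` strings (as printed for rules
        shared between methods) split into multiple sources.  When
        omitted, any prefix found on a feature token decides; a rule
        with no prefix and a single flag condition is an
        ``original_feature`` term, otherwise provenance is unknown and
        defaults to ``original_feature``.

    Raises
    ------
    RuleParseError
        On a malformed condition, unknown operator, or an interval with
        ``lower >= upper`` — the message names the offending token.
    """
    conditions: list[Condition] = []
    found_sources: list[str] = []
    for raw in text.split("&"):
        tok = raw.strip()
        if not tok:
            raise RuleParseError(f"empty condition in rule {id!r}: {text!r}")
        cond, src = _parse_condition(tok)
        conditions.append(cond)
        if src is not None and src not in found_sources:
            found_sources.append(src)
    if source is not None:
        sources = tuple(_normalize_source(s) for s in re.split(r"[/,]", source))
    elif found_sources:
        sources = tuple(found_sources)
    else:
        sources = ("original_feature",)
    return canonicalize(Rule(id=id, conditions=tuple(conditions), sources=sources))


_SOURCE_ALIASES = {
    "gradient boosting": "gradient_boosting",
    "gradient_boosting": "gradient_boosting",
    "gbdt": "gradient_boosting",
    "gbc": "gradient_boosting",
    "random forest": "random_forest",
    "random_forest": "random_forest",
    "rf": "random_forest",
    "adaboost": "adaboost",
    "ada": "adaboost",
    "original_feature": "original_feature",
    "original feature": "original_feature",
}


def _normalize_source(s: str) -> str:
    key = s.strip().lower()
    if key not in _SOURCE_ALIASES:
        raise RuleParseError(f"unknown rule source {s!r}")
    return _SOURCE_ALIASES[key]


def _parse_condition(tok: str) -> tuple[Condition, str | None]:
    m = _RE_INTERVAL.match(tok)
    if m:
        feat, src = _strip_prefix(m.group("feat").strip())
        lo, hi = _parse_number(m.group("lo")), _parse_number(m.group("hi"))
        if not lo < hi:
            raise RuleParseError(
                f"empty interval in token {tok!r}: lower {lo} >= upper {hi}"
            )
        return Condition(feat, Op.INTERVAL, lower=lo, upper=hi), src
    m = _RE_LE.match(tok)
    if m:
        feat, src = _strip_prefix(m.group("feat").strip())
        return Condition(feat, Op.LE, threshold=_parse_number(m.group("thr"))), src
    m = _RE_GT.match(tok)
    if m:
        feat, src = _strip_prefix(m.group("feat").strip())
        return Condition(feat, Op.GT, threshold=_parse_number(m.group("thr"))), src
    m = _RE_FLAG.match(tok)
    if m:
        feat, src = _strip_prefix(m.group("feat").strip())
        return Condition(feat, Op.FLAG_EQ, flag_value=int(m.group("val"))), src
    if _RE_BARE.match(tok):
        feat, src = _strip_prefix(tok)
        return Condition(feat, Op.FLAG_EQ, flag_value=1), src
    raise RuleParseError(f"cannot parse condition token {tok!r}")


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------


def canonicalize(rule: Rule) -> Rule:
    """Collapse repeated splits on one feature into a minimal conjunction.

    Per feature, LE thresholds intersect to the minimum and GT to the
    maximum; a coexisting lower bound ``> l`` and upper bound ``<= u``
    with ``l < u`` becomes the interval ``(l, u]``.  Conditions are
    sorted by feature name.  Logically empty rules (e.g. ``> 7`` with
    ``<= 3``, or contradictory flag values) raise
    :class:`EmptyRuleError`.
    """
    per_feature: dict[str, dict] = {}
    for c in rule.conditions:
        acc = per_feature.setdefault(
            c.feature, {"lower": None, "upper": None, "flag": None}
        )
        if c.op is Op.LE:
            acc["upper"] = c.threshold if acc["upper"] is None else min(acc["upper"], c.threshold)
        elif c.op is Op.GT:
            acc["lower"] = c.threshold if acc["lower"] is None else max(acc["lower"], c.threshold)
        elif c.op is Op.INTERVAL:
            acc["lower"] = c.lower if acc["lower"] is None else max(acc["lower"], c.lower)
            acc["upper"] = c.upper if acc["upper"] is None else min(acc["upper"], c.upper)
        else:
            if acc["flag"] is not None and acc["flag"] != c.flag_value:
                raise EmptyRuleError(
                    f"rule {rule.id!r}: contradictory flag values on '{c.feature}'"
                )
            acc["flag"] = c.flag_value

    out: list[Condition] = []
    for feat in sorted(per_feature):
        acc = per_feature[feat]
        lo, hi, flag = acc["lower"], acc["upper"], acc["flag"]
        if flag is not None and (lo is not None or hi is not None):
            raise EmptyRuleError(
                f"rule {rule.id!r}: '{feat}' mixes flag equality with thresholds"
            )
        if flag is not None:
            out.append(Condition(feat, Op.FLAG_EQ, flag_value=flag))
        elif lo is not None and hi is not None:
            if not lo < hi:
                raise EmptyRuleError(
                    f"rule {rule.id!r}: contradiction on '{feat}' "
                    f"(> {lo} and <= {hi} is empty)"
                )
            out.append(Condition(feat, Op.INTERVAL, lower=lo, upper=hi))
        elif hi is not None:
            out.append(Condition(feat, Op.LE, threshold=hi))
        else:
            out.append(Condition(feat, Op.GT, threshold=lo))
    return replace(rule, conditions=tuple(out))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_rule(rule: Rule, table, *, strict_missing: bool = False) -> np.ndarray:
    """Evaluate one rule on every sample, returning a 0/1 vector.

    ``table`` is a :class:`pandas.DataFrame` or a
    :class:`~rulefuse.features.FeatureTable`.  A missing (NaN) value in
    a required feature makes the rule evaluate 0 for that sample, with
    a logged warning; ``strict_missing=True`` raises instead.
    """
    df = getattr(table, "frame", table)
    out = np.ones(len(df), dtype=bool)
    for cond in rule.conditions:
        if cond.feature not in df.columns:
            raise KeyError(
                f"rule {rule.id!r} needs feature '{cond.feature}' "
                "which is not in the table"
            )
        col = df[cond.feature].to_numpy(dtype=float)
        nan = np.isnan(col)
        if nan.any():
            if strict_missing:
                raise ValueError(
                    f"missing values in feature '{cond.feature}' required "
                    f"by rule {rule.id!r}"
                )
            logger.warning(
                "rule %s: %d missing values in '%s' treated as non-firing",
                rule.id, int(nan.sum()), cond.feature,
            )
        out &= cond.holds(col) & ~nan
    return out.astype(np.int8)


def rules_to_dataset(ruleset: RuleSet, table, **kwargs) -> pd.DataFrame:
    """Stack rule indicators into a samples × rules 0/1 DataFrame.

    Column order follows the ruleset order; the index follows the
    table's sample index.
    """
    if len(ruleset) == 0:
        raise ValueError("cannot build an indicator matrix from an empty ruleset")
    df = getattr(table, "frame", table)
    cols = {r.id: evaluate_rule(r, df, **kwargs) for r in ruleset}
    return pd.DataFrame(cols, index=df.index)


def rule_support(rule: Rule, table) -> float:
    """Fraction of samples on which the rule fires."""
    df = getattr(table, "frame", table)
    if len(df) == 0:
        raise ValueError("cannot compute support on an empty table")
    return float(evaluate_rule(rule, df).mean())


def prune_conditions(rule: Rule, table, min_effect: float = 0.05) -> Rule:
    """Reduce a rule to a minimal sufficient conjunction on a table.

    Iteratively removes the condition whose removal changes the rule's
    indicator on the smallest fraction of samples, while that fraction
    is below ``min_effect``.  Conditions that barely bind are
    artefacts of the tree path a rule was harvested from, not part of
    the signal the rule captures; pruning them shortens rules and
    collapses families of path-variants onto their common core.  The
    result is re-canonicalized; single-condition rules pass through.
    """
    from dataclasses import replace as _replace

    cur = rule
    while len(cur.conditions) > 1:
        base = evaluate_rule(cur, table).astype(bool)
        best_i, best_d = None, min_effect
        for i in range(len(cur.conditions)):
            cand = _replace(
                cur, conditions=cur.conditions[:i] + cur.conditions[i + 1:]
            )
            d = float(np.mean(evaluate_rule(cand, table).astype(bool) != base))
            if d < best_d:
                best_d, best_i = d, i
        if best_i is None:
            break
        cur = _replace(
            cur, conditions=cur.conditions[:best_i] + cur.conditions[best_i + 1:]
        )
    return canonicalize(cur)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(ruleset: RuleSet) -> RuleSet:
    """Collapse rules with identical canonical condition sets.

    The surviving rule keeps the first-seen id and the union of sources
    (in first-seen order); provenance weights are kept from the first
    occurrence.  Condition order does not matter: signatures are
    computed on canonicalized rules.
    """
    seen: dict[tuple, Rule] = {}
    order: list[tuple] = []
    for r in ruleset:
        sig = r.signature()
        if sig in seen:
            prev = seen[sig]
            merged = tuple(dict.fromkeys(prev.sources + r.sources))
            seen[sig] = replace(prev, sources=merged)
        else:
            seen[sig] = r
            order.append(sig)
    return RuleSet([seen[s] for s in order])


# ---------------------------------------------------------------------------
# Text serialization: one rule per line, "id<TAB>source<TAB>rule-text"
# ---------------------------------------------------------------------------

_SOURCE_LABELS = {
    "gradient_boosting": "Gradient boosting",
    "random_forest": "Random forest",
    "adaboost": "AdaBoost",
    "original_feature": "Original feature",
}


def write_ruleset(ruleset: RuleSet, path) -> None:
    """Write a rule set as tab-separated text (id, source(s), rule)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsource\trule\n")
        for r in ruleset:
            src = "/".join(_SOURCE_LABELS[s] for s in r.sources)
            fh.write(f"{r.id}\t{src}\t{r}\n")


def read_ruleset(path) -> RuleSet:
    """Read a tab-separated rule-set file written by :func:`write_ruleset`."""
    rules: list[Rule] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("id\t"):
            raise RuleParseError(f"{path}: missing 'id<TAB>source<TAB>rule' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise RuleParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            rid, src, text = parts
            rules.append(parse_rule(text, id=rid, source=src))
    return RuleSet(rules)
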