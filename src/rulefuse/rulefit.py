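"""Sparse linear fusion of decision rules and original features.

Rules enter a penalized logistic model as 0/1 indicator columns
r_k(x); each continuous original feature enters as a winsorized,
standardized linear term l_j(x_j); binary flags pass through
unchanged.  The model

    f(x) = b0 + sum_k alpha_k r_k(x) + sum_j beta_j l_j(x_j)

is fitted with an L1 penalty on all non-intercept weights, the penalty
chosen by stratified cross-validated binomial deviance.  A rule term's
*importance* is |alpha_k| * sqrt(s_k (1 - s_k)) where s_k is its
support (the fraction of samples on which it fires); a linear term's
importance is |beta_j| * sd(l_j).  Both are the coefficient magnitude
scaled by the term's standard deviation, so importances are comparable
across rules and linear terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import PathResult, l1_logistic_path_cv
from .features import BINARY, CONTINUOUS, FeatureTable
from .rules import RuleSet, evaluate_rule, rules_to_dataset

__all__ = [
    "LinearTerm",
    "Design",
    "SparseLinearModel",
    "assemble_design",
    "fit_sparse",
    "rule_importance",
    "truncate_rules",
]


@dataclass(frozen=True)
class LinearTerm:
    """Winsorized, standardized linear term for one continuous feature.

    ``winsor_low``/``winsor_high`` are the clipping *values* (taken at
    the configured quantiles on the assembly table); ``center`` and
    ``scale`` standardize the clipped column.
    """

    feature: str
    winsor_low: float
    winsor_high: float
    center: float
    scale: float

    def __post_init__(self) -> None:
        if not self.winsor_low < self.winsor_high:
            raise ValueError("winsor_low must be < winsor_high")

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.clip(np.asarray(values, dtype=float), self.winsor_low, self.winsor_high)
        return (v - self.center) / self.scale


@dataclass
class Design:
    """Column-stacked rule indicators and linear terms with metadata."""

    matrix: pd.DataFrame
    rule_ids: list[str]
    linear_terms: list[LinearTerm]
    binary_features: list[str]
    supports: dict[str, float]            # per rule id

    @property
    def linear_names(self) -> list[str]:
        return [t.feature for t in self.linear_terms] + self.binary_features


@dataclass
class SparseLinearModel:
    intercept: float
    rule_weights: dict[str, float]
    linear_weights: dict[str, float]
    lam: float
    supports: dict[str, float]
    column_sds: dict[str, float]          # sd of each design column
    importances: dict[str, float] = field(default_factory=dict)
    path: PathResult | None = None

    def __post_init__(self) -> None:
        if not self.importances:
            self.importances = rule_importance(self)

    def predict_linear(self, design: Design) -> np.ndarray:
        z = np.full(len(design.matrix), self.intercept)
        for rid, w in self.rule_weights.items():
            z += w * design.matrix[rid].to_numpy(dtype=float)
        for name, w in self.linear_weights.items():
            z += w * design.matrix[name].to_numpy(dtype=float)
        return z

    def predict_proba(self, design: Design) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_linear(design)))


def assemble_design(
    ruleset: RuleSet,
    table: FeatureTable,
    winsor_quantiles: tuple[float, float] = (0.025, 0.975),
) -> Design:
    """Build the [rules | linear terms] design matrix.

    Continuous features are winsorized at the given quantiles and then
    standardized; binary flags pass through as 0/1 columns.  Raises if
    the assembled design is entirely constant.
    """
    lo_q, hi_q = winsor_quantiles
    if not 0.0 <= lo_q < hi_q <= 1.0:
        raise ValueError("winsor quantiles must satisfy 0 <= lo < hi <= 1")

    cols: dict[str, np.ndarray] = {}
    rule_ids: list[str] = []
    supports: dict[str, float] = {}
    if len(ruleset):
        ind = rules_to_dataset(ruleset, table)
        for rid in ind.columns:
            cols[rid] = ind[rid].to_numpy(dtype=float)
            supports[rid] = float(ind[rid].mean())
            rule_ids.append(rid)

    terms: list[LinearTerm] = []
    for feat in table.continuous_features():
        v = table.frame[feat].to_numpy(dtype=float)
        lo, hi = np.nanquantile(v, [lo_q, hi_q])
        if not lo < hi:  # (near-)constant feature: no usable linear term
            continue
        clipped = np.clip(v, lo, hi)
        sd = clipped.std()
        term = LinearTerm(feat, float(lo), float(hi), float(clipped.mean()),
                          float(sd if sd > 0 else 1.0))
        cols[feat] = term.transform(v)
        terms.append(term)
    binary = []
    for feat in table.binary_features():
        cols[feat] = table.frame[feat].to_numpy(dtype=float)
        binary.append(feat)

    mat = pd.DataFrame(cols, index=table.sample_ids)
    if mat.shape[1] == 0 or (mat.std(ddof=0) == 0).all():
        raise ValueError("degenerate design: all columns constant")
    return Design(mat, rule_ids, terms, binary, supports)


def fit_sparse(
    design: Design,
    labels,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    one_se: bool = True,
    n_folds: int = 5,
) -> SparseLinearModel:
    """L1-penalized logistic fit of the rule/linear design.

    The intercept is unpenalized.  ``one_se`` applies the
    one-standard-error rule on the cross-validated deviance curve.
    """
    y = np.asarray(labels, dtype=float)
    X = design.matrix.to_numpy(dtype=float)
    path = l1_logistic_path_cv(
        X, y, lambdas=lambda_grid, n_folds=n_folds, seed=seed, one_se=one_se
    )
    names = list(design.matrix.columns)
    coef = dict(zip(names, path.coef_selected))
    sds = {n: float(design.matrix[n].std(ddof=0)) for n in names}
    return SparseLinearModel(
        intercept=path.intercept_selected,
        rule_weights={r: float(coef[r]) for r in design.rule_ids},
        linear_weights={n: float(coef[n]) for n in design.linear_names},
        lam=path.lambda_selected,
        supports=dict(design.supports),
        column_sds=sds,
        path=path,
    )


def rule_importance(model: SparseLinearModel) -> dict[str, float]:
    """Closed-form term importances of a fitted sparse linear model.

    Rules: |alpha_k| * sqrt(s_k (1 - s_k)).  Linear terms:
    |beta_j| * sd(l_j).  Invariant to rule ids and column order.
    """
    out: dict[str, float] = {}
    for rid, a in model.rule_weights.items():
        if rid not in model.supports:
            raise ValueError(f"missing support for rule {rid!r}")
        s = model.supports[rid]
        out[rid] = abs(a) * float(np.sqrt(s * (1.0 - s)))
    for name, b in model.linear_weights.items():
        out[name] = abs(b) * model.column_sds.get(name, 0.0)
    return out


def truncate_rules(
    ruleset: RuleSet,
    table: FeatureTable,
    max_rules: int = 80,
) -> RuleSet:
    """Cap a candidate rule set as a rule *generation budget*.

    Rules are kept in extraction order — tree by tree, so for boosted
    ensembles the budget is filled by the earliest (strongest) stages,
    mirroring how RuleFit implementations size their internal tree
    ensemble to a rule budget — until ``max_rules`` non-degenerate
    rules are collected.  Rules that fire on no or on every sample of
    the table are skipped: they carry no information and would enter
    the design as constant columns.
    """
    chosen = []
    for r in ruleset:
        if len(chosen) >= max_rules:
            break
        s = float(evaluate_rule(r, table).mean())
        if 0.0 < s < 1.0:
            chosen.append(r)
    return RuleSet(chosen)
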