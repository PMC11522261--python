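"""Fusion and selection cascade for diverse decision rules.

Candidate rules from the three ensembles are filtered per source
(importance > 0.1 for the gradient-boosting and random-forest rules
fitted through the sparse linear model; |phi| > 0.4 outcome
correlation for the AdaBoost rules), merged with deduplication across
sources, subset by an L1-penalized logistic fit on the merged rule
indicators, and finally screened by per-rule SHAP contributions of
the multivariate logistic model refitted on the surviving rules.  For
a model that is linear in the indicators the
Shapley value of rule j on sample i has the exact closed form

    phi_ij = w_j * (x_ij - mean_i x_ij),

and a rule's contribution is the mean absolute phi over samples,
measured on the model's log-odds scale (a max-normalized variant is
available).  Every stage emits a SelectionTrace recording the
statistic for every input rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diagnostic
from ._glm import ebic_select, l1_logistic_path_cv
from .extract import (
    EnsembleConfig,
    extract_rules,
    extract_rules_screened,
    fit_ensembles,
)
from .features import FeatureTable
from .rulefit import SparseLinearModel, assemble_design, fit_sparse
from .rules import RuleSet, deduplicate, prune_conditions, rules_to_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionTrace",
    "CascadeResult",
    "importance_filter",
    "outcome_correlation_filter",
    "merge_rule_datasets",
    "lasso_select_rules",
    "linear_shap",
    "shap_filter",
    "phi_coefficient",
    "run_cascade",
]


@dataclass
class SelectionTrace:
    stage: str
    rules_in: list[str]
    rules_out: list[str]
    statistic: dict[str, float]
    threshold: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.rules_out) <= set(self.rules_in):
            raise ValueError("rules_out must be a subset of rules_in")
        missing = set(self.rules_in) - set(self.statistic)
        if missing:
            raise ValueError(f"statistic missing for rules: {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        out = set(self.rules_out)
        return pd.DataFrame(
            {
                "stage": self.stage,
                "rule": self.rules_in,
                "statistic": [self.statistic[r] for r in self.rules_in],
                "kept": [r in out for r in self.rules_in],
                "threshold": self.threshold,
            }
        )


def importance_filter(
    ruleset: RuleSet, model: SparseLinearModel, thr: float = 0.1
) -> SelectionTrace:
    """Keep rules whose sparse-model importance strictly exceeds thr."""
    stats = {r.id: model.importances[r.id] for r in ruleset}
    kept = [rid for rid, v in stats.items() if v > thr]
    return SelectionTrace("importance_filter", list(stats), kept, stats, thr)


def phi_coefficient(a, b) -> float:
    """Pearson correlation of two binary vectors (phi); 0 if either is
    constant (logged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        logger.warning("phi on a constant vector defined as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def outcome_correlation_filter(
    indicators: pd.DataFrame, labels, thr: float = 0.4
) -> SelectionTrace:
    """Keep rules whose |phi| with the outcome strictly exceeds thr."""
    y = np.asarray(labels, dtype=float)
    stats = {c: phi_coefficient(indicators[c], y) for c in indicators.columns}
    kept = [c for c, v in stats.items() if abs(v) > thr]
    return SelectionTrace("outcome_correlation_filter", list(stats), kept, stats, thr)


def merge_rule_datasets(
    *datasets: tuple[RuleSet, pd.DataFrame],
) -> tuple[RuleSet, pd.DataFrame]:
    """Column-concatenate rule datasets, collapsing duplicate rules.

    Duplicates (identical canonical condition sets) keep the
    first-seen column and the union of source provenances.  All
    datasets must share the same sample index.
    """
    nonempty = [(rs, ind) for rs, ind in datasets if len(rs)]
    if not nonempty:
        return RuleSet([]), pd.DataFrame()
    index = nonempty[0][1].index
    for _, ind in nonempty[1:]:
        if not ind.index.equals(index):
            raise ValueError("rule datasets have mismatched samples")
    all_rules = RuleSet([r for rs, _ in nonempty for r in rs])
    merged_rules = deduplicate(all_rules)
    columns = pd.concat([ind for _, ind in nonempty], axis=1)
    merged_ind = columns.loc[:, ~columns.columns.duplicated()][merged_rules.ids]
    return merged_rules, merged_ind


def lasso_select_rules(
    indicators: pd.DataFrame,
    labels,
    seed: int = 0,
    criterion: str = "ebic",
) -> SelectionTrace:
    """Keep rules with nonzero weight in an L1 logistic fit on the
    merged rule indicators.

    The penalty is chosen along the path by ``criterion``:
    ``"ebic"`` (default) minimizes the extended BIC — the
    support-recovery criterion, yielding the minimal rule subset whose
    fit justifies its size; ``"cv_min"`` / ``"cv_1se"`` use
    cross-validated deviance, which favours denser, more predictive
    but less parsimonious subsets.
    """
    y = np.asarray(labels, dtype=float)
    X = indicators.to_numpy(dtype=float)
    path = l1_logistic_path_cv(X, y, seed=seed, one_se=(criterion == "cv_1se"))
    if criterion == "ebic":
        path.selected = ebic_select(path, X, y)
    elif criterion not in ("cv_min", "cv_1se"):
        raise ValueError(f"unknown criterion {criterion!r}")
    signed = dict(zip(indicators.columns, path.coef_selected))
    kept = [c for c, w in signed.items() if w != 0.0]
    return SelectionTrace(
        "lasso_select", list(indicators.columns), kept,
        {k: float(abs(v)) for k, v in signed.items()},
        extra={
            "lambda": path.lambda_selected,
            "criterion": criterion,
            "weights": {k: float(v) for k, v in signed.items()},
            "intercept": path.intercept_selected,
        },
    )


def linear_shap(weights: dict[str, float], indicators: pd.DataFrame) -> pd.DataFrame:
    """Exact per-sample Shapley attributions of a linear-in-indicators
    model: phi_ij = w_j * (x_ij - mean_i x_ij)."""
    phi = {}
    for col, w in weights.items():
        x = indicators[col].to_numpy(dtype=float)
        phi[col] = w * (x - x.mean())
    return pd.DataFrame(phi, index=indicators.index)


def shap_filter(
    model,
    indicators: pd.DataFrame,
    thr: float = 0.5,
    mode: str = "auto",
) -> SelectionTrace:
    """Keep rules whose mean |SHAP| contribution is >= thr.

    ``model`` is a fitted :class:`~rulefuse.diagnostic.DiagnosticModel`
    or a plain ``{rule id: weight}`` mapping on the linear-predictor
    scale.  Contributions are mean |phi| per rule on the log-odds
    scale (the canonical output scale of linear SHAP explainers for
    logistic models).  The printed threshold of one half is
    scale-ambiguous, so three modes are offered:

    * ``"raw"`` — keep rules whose contribution is at least ``thr``
      log-odds;
    * ``"normalized"`` — rescale contributions so the largest is 1
      and threshold that;
    * ``"auto"`` (default) — keep rules passing either reading, i.e.
      threshold ``thr`` on the log-odds scale but never demand more
      than ``thr`` times the strongest rule's contribution.  This
      behaves like "raw" on sharply discriminative models and like
      "normalized" on models whose coefficients are uniformly small.

    Raw and normalized values are both recorded in the trace.
    """
    if hasattr(model, "coefficients"):
        weights = dict(model.coefficients)
    elif isinstance(model, dict):
        weights = dict(model)
    else:
        raise ValueError("shap_filter needs a fitted model or a weight mapping")
    if mode not in ("auto", "raw", "normalized"):
        raise ValueError(f"unknown shap_filter mode {mode!r}")
    phi = linear_shap(weights, indicators[list(weights)])
    raw = phi.abs().mean(axis=0)
    top = float(raw.max())
    norm = raw / top if top > 0 else raw
    if mode == "raw":
        stats = {c: float(raw[c]) for c in raw.index}
        kept = [c for c, v in stats.items() if v >= thr]
    elif mode == "normalized":
        stats = {c: float(norm[c]) for c in raw.index}
        kept = [c for c, v in stats.items() if v >= thr]
    else:
        stats = {c: float(raw[c]) for c in raw.index}
        kept = [c for c in raw.index if raw[c] >= thr or norm[c] >= thr]
    return SelectionTrace(
        "shap_filter", list(raw.index), kept, stats, thr,
        extra={
            "mode": mode,
            "raw_mean_abs_shap": {c: float(raw[c]) for c in raw.index},
            "normalized_mean_abs_shap": {c: float(norm[c]) for c in raw.index},
        },
    )


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    final_rules: RuleSet
    final_indicators: pd.DataFrame
    traces: list[SelectionTrace]
    per_method_rules: dict[str, RuleSet]
    sparse_models: dict[str, SparseLinearModel]

    def counts(self) -> dict[str, int]:
        return {t.stage + ":" + t.extra.get("method", ""): len(t.rules_out)
                for t in self.traces}


def run_cascade(
    table: FeatureTable,
    ensemble_config: EnsembleConfig | None = None,
    seed: int = 0,
    max_rules: int = 80,
    importance_thr: float = 0.1,
    correlation_thr: float = 0.4,
    shap_thr: float = 0.5,
    apply_both_filters: bool = False,
) -> CascadeResult:
    """Run the end-to-end rule extraction, fusion, and selection cascade.

    Gradient-boosting and random-forest candidates go through the
    sparse linear fusion and the importance filter; AdaBoost candidates
    go through the outcome-correlation filter (``apply_both_filters``
    subjects every source to both).  Survivors are merged with
    provenance-union deduplication, subset by a merged L1 logistic fit,
    and screened by normalized SHAP contribution.  Deterministic given
    the seed.
    """
    if table.labels is None:
        raise ValueError("the cascade needs labels")
    y = table.labels.to_numpy()
    ensembles = fit_ensembles(table, ensemble_config, seed=seed)

    traces: list[SelectionTrace] = []
    per_method: dict[str, RuleSet] = {}
    sparse_models: dict[str, SparseLinearModel] = {}
    filtered: list[tuple[RuleSet, pd.DataFrame]] = []

    for method, ensemble in ensembles.items():
        if method in ("gradient_boosting", "random_forest"):
            # the RuleFit-style rule budget applies to the two methods
            # fused through the sparse linear model; the AdaBoost pool
            # goes uncapped to the correlation filter
            candidates = extract_rules_screened(
                ensemble, table, y, max_rules=max_rules
            )
        else:
            raw = extract_rules(ensemble)
            candidates = deduplicate(
                RuleSet([prune_conditions(r, table) for r in raw])
            )
        per_method[method] = candidates
        logger.info("%s: %d candidate rules after dedup/cap", method, len(candidates))
        if len(candidates) == 0:
            continue
        indicators = rules_to_dataset(candidates, table)

        if method in ("gradient_boosting", "random_forest"):
            design = assemble_design(candidates, table)
            model = fit_sparse(design, y, seed=seed)
            sparse_models[method] = model
            trace = importance_filter(candidates, model, thr=importance_thr)
        else:
            trace = outcome_correlation_filter(indicators, y, thr=correlation_thr)
        trace.extra["method"] = method
        traces.append(trace)
        keep = trace.rules_out
        if apply_both_filters:
            other = (
                outcome_correlation_filter(indicators, y, thr=correlation_thr)
                if method in ("gradient_boosting", "random_forest")
                else None
            )
            if other is not None:
                other.extra["method"] = method
                traces.append(other)
                keep = [r for r in keep if r in set(other.rules_out)]
        filtered.append((candidates.subset(keep), indicators[keep]))

    merged_rules, merged_ind = merge_rule_datasets(*filtered)
    logger.info("merged: %d rules", len(merged_rules))
    if len(merged_rules) == 0:
        return CascadeResult(merged_rules, merged_ind, traces, per_method, sparse_models)

    lasso_trace = lasso_select_rules(merged_ind, y, seed=seed)
    lasso_trace.extra["method"] = "merged"
    traces.append(lasso_trace)
    survivors = merged_rules.subset(lasso_trace.rules_out)
    surv_ind = merged_ind[lasso_trace.rules_out]
    logger.info("post-LASSO: %d rules", len(survivors))
    if len(survivors) == 0:
        return CascadeResult(survivors, surv_ind, traces, per_method, sparse_models)

    # SHAP on the multivariate logistic model refitted over the
    # selected support (relaxed-LASSO style): the EBIC-sparse support
    # is well conditioned, and unshrunk weights give contributions on
    # the scale the model actually uses
    refit = diagnostic.fit_logistic(surv_ind, y, ruleset=survivors)
    shap_trace = shap_filter(refit, surv_ind, thr=shap_thr)
    shap_trace.extra["method"] = "merged"
    traces.append(shap_trace)
    final_ids = shap_trace.rules_out
    if not final_ids:
        # an empty rule model is unusable; keep the LASSO support
        logger.warning(
            "SHAP filter removed every rule; keeping the %d LASSO-selected "
            "rules instead", len(survivors),
        )
        final_ids = list(survivors.ids)
    final_rules = survivors.subset(final_ids)
    final_ind = surv_ind[final_ids]
    logger.info("final: %d rules", len(final_rules))
    return CascadeResult(final_rules, final_ind, traces, per_method, sparse_models)
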