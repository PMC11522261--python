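"""Rule-based multivariate logistic diagnostic model and its evaluation.

The final model is an ordinary logistic regression over the selected
rule indicators,

    Y_i = b0 + sum_k c_k r_k(x_i),    P(outcome = 1 | x_i) = sigmoid(Y_i),

rendered for clinicians as a signed-coefficient equation plus a rule
table.  Evaluation reports AUC with a DeLong (default) or stratified
bootstrap confidence interval, plus threshold metrics (accuracy,
precision, recall, F1) from the confusion matrix at a probability
cutoff.  The published 15-rule lung-adenocarcinoma model (IAC vs
MIA/AIS) ships as a fixture via :func:`published_model`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .rules import RuleSet, read_ruleset

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticModel",
    "EvaluationReport",
    "fit_logistic",
    "linear_predictor",
    "predict_proba",
    "auc_score",
    "delong_ci",
    "evaluate",
    "export_model_card",
    "load_model_card",
    "published_model",
    "published_ruleset",
]


@dataclass
class DiagnosticModel:
    intercept: float
    coefficients: dict[str, float]
    ruleset: RuleSet | None = None
    threshold: float = 0.5
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ruleset is not None:
            if set(self.coefficients) != set(self.ruleset.ids):
                raise ValueError("coefficient ids must match the ruleset ids")


@dataclass
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    confusion: dict[str, int]             # tp, fp, tn, fn
    roc_points: pd.DataFrame              # fpr, tpr, cutoff

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "ci_method": self.ci_method,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
            **{k: int(v) for k, v in self.confusion.items()},
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_logistic(
    indicators: pd.DataFrame,
    labels,
    ruleset: RuleSet | None = None,
    ridge: float = 1e-6,
) -> DiagnosticModel:
    """Maximum-likelihood logistic fit over rule indicator columns.

    Constant columns get a zero coefficient and are excluded from the
    fit.  On perfect separation or non-convergence — easy to hit with
    binary designs at small n — the model is refitted with a small
    ridge penalty and a warning is logged.
    """
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    names = list(indicators.columns)
    X = indicators.to_numpy(dtype=float)
    active = X.std(axis=0) > 0
    coefs = dict.fromkeys(names, 0.0)
    diagnostics: dict = {"ridge_fallback": False, "dropped_constant": [
        n for n, a in zip(names, active) if not a
    ]}

    if not active.any():
        intercept = float(np.log(y.mean() / (1.0 - y.mean())))
        return DiagnosticModel(intercept, coefs, ruleset, diagnostics=diagnostics)

    Xa = X[:, active]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, sm.add_constant(Xa)).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("MLE did not converge")
        params = res.params
        intercept, beta = float(params[0]), params[1:]
        diagnostics["converged"] = True
    except Exception as err:  # separation / singularity / non-convergence
        logger.warning("logistic MLE failed (%s); refitting with ridge %.1e", err, ridge)
        clf = LogisticRegression(l1_ratio=0.0, C=1.0 / ridge, max_iter=5000)
        clf.fit(Xa, y)
        intercept, beta = float(clf.intercept_[0]), clf.coef_[0]
        diagnostics["ridge_fallback"] = True
        diagnostics["mle_error"] = str(err)

    for n, b in zip([n for n, a in zip(names, active) if a], beta):
        coefs[n] = float(b)
    return DiagnosticModel(intercept, coefs, ruleset, diagnostics=diagnostics)


def linear_predictor(model: DiagnosticModel, indicators: pd.DataFrame) -> np.ndarray:
    """Y_i = intercept + sum_k coef_k * r_k(x_i)."""
    missing = set(model.coefficients) - set(indicators.columns)
    if missing:
        raise KeyError(f"indicator matrix is missing rule columns: {sorted(missing)}")
    z = np.full(len(indicators), model.intercept)
    for rid, c in model.coefficients.items():
        z += c * indicators[rid].to_numpy(dtype=float)
    return z


def predict_proba(model: DiagnosticModel, indicators: pd.DataFrame) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-linear_predictor(model, indicators)))


# ---------------------------------------------------------------------------
# AUC, DeLong, evaluation
# ---------------------------------------------------------------------------


def auc_score(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) AUC with tie correction."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores, labels) -> tuple[float, float]:
    """DeLong AUC and its variance (structural components on midranks)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / (m * n)) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:m] - tx) / n            # per-positive structural component
    v10 = 1.0 - (tz[m:] - ty) / m      # per-negative structural component
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return float(auc), float(var)


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong normal-approximation confidence interval."""
    auc, var = delong_variance(scores, labels)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return auc, (lo, hi)


def bootstrap_ci(
    scores, labels, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Stratified bootstrap percentile CI for the AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos_idx, len(pos_idx)),
            rng.choice(neg_idx, len(neg_idx)),
        ])
        aucs[b] = auc_score(scores[idx], y[idx])
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return auc_score(scores, y), (float(lo), float(hi))


def evaluate(
    model: DiagnosticModel,
    indicators: pd.DataFrame,
    labels,
    ci_method: str = "delong",
    threshold: float | None = None,
    youden: bool = False,
    seed: int = 0,
) -> EvaluationReport:
    """Full discrimination report for a diagnostic model on a dataset.

    ``youden=True`` replaces the fixed probability cutoff with the
    ROC point maximizing TPR − FPR.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("evaluation needs both classes")
    proba = predict_proba(model, indicators)

    if ci_method == "delong":
        auc, ci = delong_ci(proba, y)
    elif ci_method == "bootstrap":
        auc, ci = bootstrap_ci(proba, y, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    fpr, tpr, cuts = roc_curve(y, proba)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "cutoff": cuts})
    if youden:
        threshold = float(cuts[np.argmax(tpr - fpr)])
    elif threshold is None:
        threshold = model.threshold

    pred = (proba >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(
        auc=auc,
        auc_ci=ci,
        ci_method=ci_method,
        accuracy=(tp + tn) / len(y),
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc_points=roc_points,
    )


# ---------------------------------------------------------------------------
# Model card
# ---------------------------------------------------------------------------


def export_model_card(model: DiagnosticModel) -> str:
    """Render the model as a human-readable card with an embedded
    machine-readable block; :func:`load_model_card` round-trips it."""
    lines = ["# Rule-based diagnostic model", "", "## Equation", ""]
    eq = f"Y = {model.intercept:+.4f}"
    for rid, c in model.coefficients.items():
        eq += f" {'-' if c < 0 else '+'} {abs(c):.4f} × {rid}"
    lines += [eq, "", "P(outcome = 1) = 1 / (1 + exp(-Y))", ""]
    if model.ruleset is not None:
        lines += ["## Rules", "", "id\tsource\trule"]
        for r in model.ruleset:
            src = "/".join(r.sources)
            lines.append(f"{r.id}\t{src}\t{r}")
        lines.append("")
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "threshold": model.threshold,
        "rules": (
            {r.id: {"text": str(r), "sources": list(r.sources)} for r in model.ruleset}
            if model.ruleset is not None else None
        ),
    }
    lines += ["## Machine-readable", "", "```json",
              json.dumps(payload, indent=2), "```", ""]
    return "\n".join(lines)


def load_model_card(text: str) -> DiagnosticModel:
    """Reconstruct a model from the card's machine-readable block."""
    start = text.index("```json") + len("```json")
    end = text.index("```", start)
    payload = json.loads(text[start:end])
    ruleset = None
    if payload.get("rules"):
        from .rules import parse_rule

        ruleset = RuleSet([
            parse_rule(info["text"], id=rid, source="/".join(info["sources"]))
            for rid, info in payload["rules"].items()
        ])
    return DiagnosticModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        ruleset=ruleset,
        threshold=float(payload.get("threshold", 0.5)),
    )


# ---------------------------------------------------------------------------
# Published fixture
# ---------------------------------------------------------------------------


def published_ruleset() -> RuleSet:
    """The published 15-rule set (IAC vs MIA/AIS), parsed from the
    packaged rule table."""
    path = resources.files("rulefuse.data") / "published_rules.tsv"
    with resources.as_file(path) as p:
        return read_ruleset(p)


def published_model() -> DiagnosticModel:
    """The published 15-rule logistic model with its printed
    coefficients."""
    path = resources.files("rulefuse.data") / "published_model.json"
    payload = json.loads(path.read_text(encoding="utf-8"))
    return DiagnosticModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        ruleset=published_ruleset(),
        threshold=float(payload.get("threshold", 0.5)),
    )
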