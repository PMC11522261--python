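"""End-to-end workflow: feature selection → rule extraction → fusion →
diagnostic model → evaluation, with reproducible artifacts.

Every run writes delimited-text artifacts plus a manifest (config
hash, seed, package version) so a run can be replayed bit-identically
from the manifest and inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostic import evaluate, export_model_card, fit_logistic
from .extract import EnsembleConfig
from .features import FeatureTable, select_features
from .rules import rules_to_dataset, write_ruleset
from .select import run_cascade

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "train_test_split_table"]


@dataclass
class RunConfig:
    """All stage parameters of the workflow, with reference defaults
    (Spearman cutoff 0.9, mRMR top-100, 500 LASSO repeats, importance
    0.1, correlation 0.4, SHAP 0.5, rule cap 80, and the ensemble
    settings of :class:`~rulefuse.extract.EnsembleConfig`)."""

    seed: int = 0
    label_col: str = "outcome"
    run_feature_selection: bool = True
    variance_tol: float = 1e-8
    rho_cutoff: float = 0.9
    mrmr_k: int = 100
    lasso_iters: int = 500
    max_features: int = 10
    importance_thr: float = 0.1
    correlation_thr: float = 0.4
    shap_thr: float = 0.5
    max_rules: int = 80
    test_fraction: float = 0.0
    ensembles: EnsembleConfig = field(default_factory=EnsembleConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ens = EnsembleConfig(**raw.pop("ensembles", {}))
        return cls(ensembles=ens, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def train_test_split_table(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified split preserving label prevalence."""
    from sklearn.model_selection import train_test_split

    idx_train, idx_test = train_test_split(
        table.frame.index,
        test_size=test_fraction,
        stratify=table.labels,
        random_state=seed,
    )
    def take(idx):
        return FeatureTable(
            table.frame.loc[idx].copy(),
            labels=table.labels.loc[idx],
            kinds=dict(table.kinds),
        )
    return take(idx_train), take(idx_test)


def run_pipeline(table: FeatureTable, config: RunConfig, outdir) -> dict:
    """Execute the full workflow and write all artifacts to ``outdir``.

    Returns a summary dict (selected features, rule counts, evaluation
    metrics, artifact paths).  Any stage failure propagates with the
    stage name prefixed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table.labels is None:
        raise ValueError(f"pipeline: label column '{config.label_col}' missing")

    artifacts: dict[str, str] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage '{name}' failed: {err}") from err

    if config.run_feature_selection:
        selected, reports = _stage(
            "select-features",
            select_features,
            table,
            variance_tol=config.variance_tol,
            rho_cutoff=config.rho_cutoff,
            mrmr_k=config.mrmr_k,
            lasso_iters=config.lasso_iters,
            seed=config.seed,
            max_features=config.max_features,
        )
        pd.concat([r.to_frame() for r in reports]).to_csv(
            outdir / "feature_selection_report.csv", index=False
        )
        artifacts["feature_selection_report"] = "feature_selection_report.csv"
    else:
        selected = table

    selected.to_csv(outdir / "selected_features.csv", label_col=config.label_col)
    artifacts["selected_features"] = "selected_features.csv"

    if config.test_fraction > 0:
        train, test = train_test_split_table(selected, config.test_fraction, config.seed)
    else:
        train, test = selected, None

    cascade = _stage(
        "fuse",
        run_cascade,
        train,
        ensemble_config=config.ensembles,
        seed=config.seed,
        max_rules=config.max_rules,
        importance_thr=config.importance_thr,
        correlation_thr=config.correlation_thr,
        shap_thr=config.shap_thr,
    )
    write_ruleset(cascade.final_rules, outdir / "final_rules.tsv")
    artifacts["final_rules"] = "final_rules.tsv"
    pd.concat([t.to_frame() for t in cascade.traces]).to_csv(
        outdir / "selection_trace.csv", index=False
    )
    artifacts["selection_trace"] = "selection_trace.csv"

    model = _stage(
        "fit", fit_logistic, cascade.final_indicators,
        train.labels.to_numpy(), ruleset=cascade.final_rules,
    )
    (outdir / "model_card.md").write_text(export_model_card(model), encoding="utf-8")
    artifacts["model_card"] = "model_card.md"

    eval_table = test if test is not None else train
    ind_eval = rules_to_dataset(cascade.final_rules, eval_table)
    report = _stage(
        "evaluate", evaluate, model, ind_eval, eval_table.labels.to_numpy(),
    )
    (outdir / "evaluation.json").write_text(
        json.dumps(report.to_dict(), indent=2), encoding="utf-8"
    )
    report.roc_points.to_csv(outdir / "roc_points.csv", index=False)
    artifacts["evaluation"] = "evaluation.json"
    artifacts["roc_points"] = "roc_points.csv"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_samples": table.n_samples,
        "selected_features": selected.feature_names,
        "rule_counts": {m: len(rs) for m, rs in cascade.per_method_rules.items()},
        "final_rule_count": len(cascade.final_rules),
        "evaluation": report.to_dict(),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest
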