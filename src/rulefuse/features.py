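"""Two-phase feature selection for high-dimensional radiomics tables.

Phase 1 reduces redundancy among the continuous radiomic signatures:
scaling normalization, near-zero-variance removal, pairwise Spearman
pruning at |rho| > 0.9, then minimum-redundancy-maximum-relevance
(mRMR) ranking to a top-k shortlist.  Phase 2 merges the shortlist with
the binary radiological flags (which bypass phase 1) and runs repeated
L1-penalized logistic selection — stability selection over re-randomized
cross-validation folds — keeping features by selection frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from ._glm import l1_logistic_path_cv

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class FeatureTable:
    """A samples × features matrix with per-column kind and 0/1 labels."""

    frame: pd.DataFrame
    labels: pd.Series | None = None
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dups = sorted(self.frame.columns[self.frame.columns.duplicated()])
            raise ValueError(f"duplicate feature names: {dups}")
        if not self.kinds:
            self.kinds = {c: self._infer_kind(self.frame[c]) for c in self.frame.columns}
        for col, kind in self.kinds.items():
            if kind == BINARY:
                vals = set(self.frame[col].dropna().unique())
                if not vals <= {0, 1, 0.0, 1.0}:
                    raise ValueError(f"binary feature '{col}' has values outside {{0,1}}")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.frame.index).astype(int)
            if not set(self.labels.unique()) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    @staticmethod
    def _infer_kind(col: pd.Series) -> str:
        vals = set(col.dropna().unique())
        return BINARY if vals <= {0, 1, 0.0, 1.0} else CONTINUOUS

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def continuous_features(self) -> list[str]:
        return [c for c in self.frame.columns if self.kinds[c] == CONTINUOUS]

    def binary_features(self) -> list[str]:
        return [c for c in self.frame.columns if self.kinds[c] == BINARY]

    def subset(self, features) -> "FeatureTable":
        features = list(features)
        return FeatureTable(
            self.frame[features].copy(),
            labels=self.labels,
            kinds={f: self.kinds[f] for f in features},
        )

    # -- delimited-text I/O --------------------------------------------------

    @classmethod
    def read_csv(cls, path, label_col: str = "outcome", sep: str = ",") -> "FeatureTable":
        df = pd.read_csv(path, sep=sep)
        if label_col is not None and label_col not in df.columns:
            raise KeyError(f"label column '{label_col}' not found in {path}")
        labels = df.pop(label_col) if label_col is not None else None
        return cls(df, labels=labels)

    def to_csv(self, path, label_col: str = "outcome", sep: str = ",") -> None:
        df = self.frame.copy()
        if self.labels is not None:
            df[label_col] = self.labels.values
        df.to_csv(path, sep=sep, index=False)


@dataclass
class SelectionReport:
    """Audit record for one selection stage."""

    stage: str
    kept: list[str]
    removed: list[tuple[str, str]]          # (feature, reason)
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def removed_names(self) -> list[str]:
        return [f for f, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": self.stage, "feature": f, "kept": f in set(self.kept),
             "score": self.scores.get(f, float("nan")),
             "reason": dict(self.removed).get(f, "")}
            for f in self.kept + self.removed_names
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase-1 stages
# ---------------------------------------------------------------------------


def scale_features(table: FeatureTable) -> FeatureTable:
    """Standardize continuous columns to mean 0, sd 1 (population sd).

    Zero-variance columns pass through unchanged and are logged; binary
    columns are untouched.  Idempotent up to floating-point error.
    """
    if table.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    df = table.frame.copy()
    for col in table.continuous_features():
        v = df[col].to_numpy(dtype=float)
        sd = np.nanstd(v)
        if sd == 0.0 or np.isnan(sd):
            logger.warning("constant column '%s' left unscaled", col)
            continue
        df[col] = (v - np.nanmean(v)) / sd
    return FeatureTable(df, labels=table.labels, kinds=dict(table.kinds))


def variance_filter(table: FeatureTable, tol: float = 1e-8) -> SelectionReport:
    """Drop continuous features whose (pre-scaling) variance is <= tol."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    kept, removed, scores = [], [], {}
    for col in table.feature_names:
        if table.kinds[col] != CONTINUOUS:
            kept.append(col)
            continue
        var = float(np.nanvar(table.frame[col].to_numpy(dtype=float)))
        scores[col] = var
        if var <= tol:
            removed.append((col, f"variance {var:.3g} <= {tol:.3g}"))
        else:
            kept.append(col)
    if not kept:
        raise ValueError("variance filter removed every feature")
    return SelectionReport("variance_filter", kept, removed, scores)


def correlation_prune(table: FeatureTable, cutoff: float = 0.9) -> SelectionReport:
    """Greedy Spearman pruning of strongly inter-correlated features.

    Pairs with |rho| > cutoff are visited in decreasing |rho|; within a
    pair the feature with the larger mean absolute correlation to all
    remaining features is dropped (ties go to the lexicographically
    later name), until no pair exceeds the cutoff.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    names = list(table.feature_names)
    # Spearman = Pearson on ranks; constant columns give nan -> treat as 0
    ranks = table.frame[names].rank().to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        R = np.abs(np.corrcoef(ranks, rowvar=False))
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)

    active = np.ones(len(names), dtype=bool)
    removed: list[tuple[str, str]] = []
    while True:
        sub = R * np.outer(active, active)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i, active].sum() / max(active.sum() - 1, 1)
        mean_j = sub[j, active].sum() / max(active.sum() - 1, 1)
        if mean_i > mean_j:
            drop, other = i, j
        elif mean_j > mean_i:
            drop, other = j, i
        else:  # tie: drop the lexicographically later name
            drop, other = (i, j) if names[i] > names[j] else (j, i)
        active[drop] = False
        removed.append(
            (names[drop],
             f"|rho|={sub[i, j]:.3f} with '{names[other]}' > {cutoff}")
        )
    kept = [n for n, a in zip(names, active) if a]
    scores = {n: float(R[k][active].max()) if active.sum() > 1 else 0.0
              for k, n in enumerate(names)}
    return SelectionReport("correlation_prune", kept, removed, scores)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------


def _discretize(col: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning for mutual-information estimation."""
    vals = pd.Series(col)
    if vals.nunique() <= bins:
        codes, _ = pd.factorize(vals)
        return codes
    return pd.qcut(vals, bins, labels=False, duplicates="drop").to_numpy()


def mrmr_rank(
    table: FeatureTable,
    k: int = 100,
    redundancy_weight: float = 1.0,
    bins: int = 10,
) -> SelectionReport:
    """Greedy mRMR ranking (difference form) with discretized MI.

    The first feature maximizes relevance I(f; y); each subsequent one
    maximizes I(f; y) − w · mean over selected s of I(f; s), with
    continuous features discretized into equal-frequency bins.  Returns
    min(k, p) features in selection order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.labels is None:
        raise ValueError("mRMR needs labels")
    names = list(table.feature_names)
    y = table.labels.to_numpy()
    disc = {
        n: _discretize(table.frame[n].to_numpy(dtype=float), bins)
        for n in names
    }
    relevance = {n: mutual_info_score(disc[n], y) for n in names}

    selected: list[str] = []
    scores: dict[str, float] = {}
    pair_mi: dict[tuple[str, str], float] = {}
    candidates = set(names)
    while candidates and len(selected) < min(k, len(names)):
        best_name, best_score = None, -np.inf
        for n in sorted(candidates):
            if selected and redundancy_weight != 0.0:
                red = 0.0
                for s in selected:
                    key = (n, s)
                    if key not in pair_mi:
                        pair_mi[key] = mutual_info_score(disc[n], disc[s])
                    red += pair_mi[key]
                score = relevance[n] - redundancy_weight * red / len(selected)
            else:
                score = relevance[n]
            if score > best_score:
                best_name, best_score = n, score
        selected.append(best_name)
        scores[best_name] = float(best_score)
        candidates.discard(best_name)
    removed = [(n, "below mRMR top-k") for n in names if n not in set(selected)]
    return SelectionReport("mrmr_rank", selected, removed, scores)


# ---------------------------------------------------------------------------
# Repeated LASSO (stability selection)
# ---------------------------------------------------------------------------


def repeated_lasso_select(
    table: FeatureTable,
    n_iter: int = 500,
    seed: int = 0,
    stability_threshold: float = 0.5,
    max_features: int | None = 10,
    n_folds: int = 5,
) -> SelectionReport:
    """Stability selection by repeated L1-penalized logistic fits.

    Each iteration re-randomizes the stratified CV folds, fits the
    penalty path, and records the support at the one-standard-error
    lambda.  Features selected in at least ``stability_threshold`` of
    the iterations are kept, ordered by selection frequency (ties by
    name), optionally truncated to ``max_features``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if table.labels is None:
        raise ValueError("selection needs labels")
    y = table.labels.to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    names = list(table.feature_names)
    X = table.frame[names].to_numpy(dtype=float)

    counts = np.zeros(len(names))
    for it in range(n_iter):
        path = l1_logistic_path_cv(
            X, y, n_folds=n_folds, seed=seed + it, one_se=True
        )
        counts += path.coef_selected != 0.0
    freq = counts / n_iter
    scores = dict(zip(names, freq.astype(float)))

    order = sorted(range(len(names)), key=lambda i: (-freq[i], names[i]))
    kept = [names[i] for i in order if freq[i] >= stability_threshold]
    if max_features is not None:
        kept = kept[:max_features]
    removed = [
        (n, f"selection frequency {scores[n]:.2f} below cut")
        for n in names if n not in set(kept)
    ]
    return SelectionReport("repeated_lasso", kept, removed, scores)


# ---------------------------------------------------------------------------
# Full two-phase pipeline
# ---------------------------------------------------------------------------


def select_features(
    table: FeatureTable,
    variance_tol: float = 1e-8,
    rho_cutoff: float = 0.9,
    mrmr_k: int = 100,
    lasso_iters: int = 500,
    seed: int = 0,
    stability_threshold: float = 0.5,
    max_features: int | None = 10,
    radiological: list[str] | None = None,
) -> tuple[FeatureTable, list[SelectionReport]]:
    """Run the two-phase pipeline and return (reduced table, reports).

    Binary radiological flags (``radiological``, default: every binary
    column) bypass phase 1 and are merged with the mRMR shortlist
    before the repeated-LASSO phase.  Deterministic given the seed.
    """
    if radiological is None:
        radiological = table.binary_features()
    radiomic = [f for f in table.feature_names if f not in set(radiological)]

    # near-zero variance is a property of the raw features: scaling
    # would renormalize every non-constant column to unit variance
    rep_var = variance_filter(table.subset(radiomic), tol=variance_tol)
    phase1 = scale_features(table.subset(rep_var.kept))
    rep_rho = correlation_prune(phase1, cutoff=rho_cutoff)
    phase1 = phase1.subset(rep_rho.kept)
    rep_mrmr = mrmr_rank(phase1, k=mrmr_k)
    shortlist = rep_mrmr.kept

    merged = table.subset(shortlist + list(radiological))
    merged = scale_features(merged)
    rep_lasso = repeated_lasso_select(
        merged,
        n_iter=lasso_iters,
        seed=seed,
        stability_threshold=stability_threshold,
        max_features=max_features,
    )
    reports = [rep_var, rep_rho, rep_mrmr, rep_lasso]
    for r in reports:
        logger.info("%s: kept %d, removed %d", r.stage, len(r.kept), len(r.removed))
    return table.subset(rep_lasso.kept), reports
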