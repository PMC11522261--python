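"""Tree ensembles and root-to-node rule extraction.

Three ensemble architectures generate candidate rules with different
semantics: gradient boosting and AdaBoost produce *weighted,
sequentially correlated* trees (each tree enters the ensemble with a
stagewise weight), while a random forest averages *equal, independent*
trees.  Every non-root node of every tree yields one candidate rule —
the conjunction of the split decisions on its path from the root — so
a tree with N nodes contributes N − 1 rules of length 1 up to its
depth.  Left branches test ``feature <= threshold``, right branches
``feature > threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .rules import Condition, Op, Rule, RuleSet, canonicalize

__all__ = [
    "TreeNode",
    "TreeEnsemble",
    "EnsembleConfig",
    "fit_ensembles",
    "extract_rules",
    "from_sklearn_tree",
]


@dataclass
class TreeNode:
    """Binary tree node with axis-aligned '<= threshold' split semantics."""

    depth: int
    split_feature: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def __post_init__(self) -> None:
        if (self.left is None) != (self.right is None):
            raise ValueError("internal nodes must have both children")
        if not self.is_leaf and (
            self.split_feature is None or self.split_threshold is None
        ):
            raise ValueError("internal nodes need a split feature and threshold")

    def count_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.count_nodes() + self.right.count_nodes()


@dataclass
class TreeEnsemble:
    """Trees plus per-tree weights and a combination mode.

    ``boosted_weighted`` ensembles (gradient boosting, AdaBoost) carry
    stagewise weights beta_m; ``averaged`` ensembles (random forest)
    carry uniform weights 1/M.
    """

    trees: list[TreeNode]
    tree_weights: list[float]
    mode: str                      # "boosted_weighted" | "averaged"
    method_tag: str                # "gradient_boosting" | "random_forest" | "adaboost"

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.tree_weights):
            raise ValueError("one weight per tree required")
        if self.mode not in ("boosted_weighted", "averaged"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "averaged" and self.trees:
            expected = 1.0 / len(self.trees)
            if not np.allclose(self.tree_weights, expected):
                raise ValueError("averaged mode requires uniform weights 1/M")

    @property
    def M(self) -> int:
        return len(self.trees)


def from_sklearn_tree(sk_tree, feature_names: list[str]) -> TreeNode:
    """Convert a fitted sklearn tree (``.tree_``) to a TreeNode."""
    t = sk_tree.tree_

    def build(idx: int, depth: int) -> TreeNode:
        if t.children_left[idx] == -1:
            return TreeNode(depth=depth)
        return TreeNode(
            depth=depth,
            split_feature=feature_names[t.feature[idx]],
            split_threshold=float(t.threshold[idx]),
            left=build(t.children_left[idx], depth + 1),
            right=build(t.children_right[idx], depth + 1),
        )

    return build(0, 0)


@dataclass
class EnsembleConfig:
    """Hyperparameters of the three rule-generating ensembles.

    Defaults are the reference configuration used throughout:
    gradient boosting with 500 depth-5 trees at learning rate 0.1, a
    500-tree forest with minimum leaf size 1, and 30 depth-5 discrete
    (SAMME) AdaBoost trees.
    """

    gb_n_estimators: int = 500
    gb_max_depth: int = 5
    gb_learning_rate: float = 0.1
    rf_n_estimators: int = 500
    rf_min_samples_leaf: int = 1
    ada_n_estimators: int = 30
    ada_max_depth: int = 5


def fit_ensembles(
    table: FeatureTable,
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> dict[str, TreeEnsemble]:
    """Fit the three ensembles and wrap them with their weight semantics.

    Returns a dict keyed by method tag.  Per-tree weights: the learning
    rate for every gradient-boosting stage, 1/M for forest trees, and
    the SAMME log-odds stage weights for AdaBoost.  Deterministic given
    the seed.
    """
    if config is None:
        config = EnsembleConfig()
    if table.labels is None:
        raise ValueError("fitting needs labels")
    y = table.labels.to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    X = table.frame.to_numpy(dtype=float)
    names = table.feature_names

    gb = GradientBoostingClassifier(
        n_estimators=config.gb_n_estimators,
        max_depth=config.gb_max_depth,
        learning_rate=config.gb_learning_rate,
        random_state=seed,
    ).fit(X, y)
    rf = RandomForestClassifier(
        n_estimators=config.rf_n_estimators,
        min_samples_leaf=config.rf_min_samples_leaf,
        random_state=seed,
    ).fit(X, y)
    # SAMME discrete boosting is the only behaviour of this estimator
    ada = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=config.ada_max_depth),
        n_estimators=config.ada_n_estimators,
        random_state=seed,
    ).fit(X, y)

    gb_trees = [from_sklearn_tree(est[0], names) for est in gb.estimators_]
    rf_trees = [from_sklearn_tree(est, names) for est in rf.estimators_]
    ada_trees = [from_sklearn_tree(est, names) for est in ada.estimators_]
    ada_weights = [float(w) for w in ada.estimator_weights_[: len(ada_trees)]]

    return {
        "gradient_boosting": TreeEnsemble(
            gb_trees,
            [config.gb_learning_rate] * len(gb_trees),
            mode="boosted_weighted",
            method_tag="gradient_boosting",
        ),
        "random_forest": TreeEnsemble(
            rf_trees,
            [1.0 / len(rf_trees)] * len(rf_trees),
            mode="averaged",
            method_tag="random_forest",
        ),
        "adaboost": TreeEnsemble(
            ada_trees,
            ada_weights,
            mode="boosted_weighted",
            method_tag="adaboost",
        ),
    }


def extract_rules(
    ensemble: TreeEnsemble, min_depth: int = 1, max_rules: int | None = None
) -> RuleSet:
    """One candidate rule per non-root node of every tree.

    Each rule's conditions are the canonicalized split decisions on the
    path from the root to that node; its provenance weight is the
    owning tree's stage weight.  Rules from paths shallower than
    ``min_depth`` are skipped.  Extraction is deterministic: node order
    follows a left-first depth-first walk, tree by tree.  ``max_rules``
    stops extraction once that many candidates have been collected
    (whole ensembles can hold hundreds of thousands of paths).
    """
    if not ensemble.trees:
        raise ValueError("cannot extract rules from an empty ensemble")
    rules: list[Rule] = []
    for ti, (root, w) in enumerate(zip(ensemble.trees, ensemble.tree_weights)):
        if max_rules is not None and len(rules) >= max_rules:
            break
        counter = [0]

        def walk(node: TreeNode, path: list[Condition]) -> None:
            if node.is_leaf:
                return
            if max_rules is not None and len(rules) >= max_rules:
                return
            for branch_op, child in ((Op.LE, node.left), (Op.GT, node.right)):
                cond = Condition(
                    node.split_feature, branch_op, threshold=node.split_threshold
                )
                new_path = path + [cond]
                if len(new_path) >= min_depth:
                    counter[0] += 1
                    rules.append(
                        canonicalize(
                            Rule(
                                id=f"{ensemble.method_tag}_t{ti}_n{counter[0]}",
                                conditions=tuple(new_path),
                                sources=(ensemble.method_tag,),
                                provenance_weight=w,
                            )
                        )
                    )
                walk(child, new_path)

        walk(root, [])
    return RuleSet(rules)


def extract_rules_screened(
    ensemble: TreeEnsemble,
    table,
    labels,
    max_rules: int = 80,
    redundancy_jaccard: float = 0.95,
    shallow_depth: int = 2,
    deep_candidate_cap: int = 800,
    prune_min_effect: float | None = 0.05,
) -> RuleSet:
    """Screen the ensemble's candidate paths down to a diverse rule budget.

    Candidates are every distinct, non-degenerate rule of length up to
    ``shallow_depth`` from every tree (a whole boosted ensemble holds
    thousands of near-copies of its strongest splits), plus deeper
    paths in tree order up to ``deep_candidate_cap``.  Candidates are
    ranked by |phi| correlation with the outcome and kept greedily,
    skipping any whose indicator has Jaccard overlap of at least
    ``redundancy_jaccard`` with an already-kept rule — so the budget
    is filled with the strongest available version of each distinct
    signal instead of many threshold-jittered copies of the single
    strongest one.  The kept rules are finally pruned to minimal
    sufficient conjunctions (conditions changing a rule's firing
    pattern on less than ``prune_min_effect`` of samples are dropped)
    and re-deduplicated.  Deterministic (ties resolved by candidate
    order).
    """
    if not ensemble.trees:
        raise ValueError("cannot extract rules from an empty ensemble")
    from .rules import evaluate_rule, prune_conditions

    y = np.asarray(labels, dtype=float)
    seen: set[tuple] = set()
    cands: list[Rule] = []
    vecs: list[np.ndarray] = []

    def consider(path: list[Condition], ti: int, w: float) -> None:
        rule = canonicalize(
            Rule(
                id=f"{ensemble.method_tag}_t{ti}_c{len(seen)}",
                conditions=tuple(path),
                sources=(ensemble.method_tag,),
                provenance_weight=w,
            )
        )
        sig = rule.signature()
        if sig in seen:
            return
        seen.add(sig)
        v = evaluate_rule(rule, table).astype(bool)
        if not 0 < v.sum() < len(v):
            return
        cands.append(rule)
        vecs.append(v)

    for d in range(1, shallow_depth + 1):
        for ti, (root, w) in enumerate(zip(ensemble.trees, ensemble.tree_weights)):
            for path in _paths_at_depth(root, d):
                consider(path, ti, w)
    n_shallow = len(cands)
    for ti, (root, w) in enumerate(zip(ensemble.trees, ensemble.tree_weights)):
        if len(cands) - n_shallow >= deep_candidate_cap:
            break
        for path in _paths_deeper_than(root, shallow_depth):
            consider(path, ti, w)
            if len(cands) - n_shallow >= deep_candidate_cap:
                break

    if not cands:
        return RuleSet([])
    M = np.stack(vecs)                       # candidates × samples, bool
    Mf = M.astype(float)
    sd = Mf.std(axis=1)
    yc = (y - y.mean())
    ysd = y.std()
    phi = np.abs((Mf - Mf.mean(axis=1, keepdims=True)) @ yc) / (
        len(y) * np.where(sd > 0, sd, 1.0) * (ysd if ysd > 0 else 1.0)
    )
    order = np.argsort(-phi, kind="stable")
    kept_idx: list[int] = []
    sizes = M.sum(axis=1)
    for i in order:
        if len(kept_idx) >= max_rules:
            break
        redundant = False
        for k in kept_idx:
            inter = int(np.count_nonzero(M[i] & M[k]))
            union = sizes[i] + sizes[k] - inter
            if union > 0 and inter / union >= redundancy_jaccard:
                redundant = True
                break
        if not redundant:
            kept_idx.append(int(i))
    kept_idx.sort()
    kept = [cands[i] for i in kept_idx]
    if prune_min_effect:
        from .rules import deduplicate

        kept = [prune_conditions(r, table, min_effect=prune_min_effect) for r in kept]
        return deduplicate(RuleSet(kept))
    return RuleSet(kept)


def _paths_deeper_than(root: TreeNode, depth: int):
    """Yield condition paths strictly longer than ``depth``, left-first."""

    def walk(node: TreeNode, path: list[Condition]):
        if node.is_leaf:
            return
        for op, child in ((Op.LE, node.left), (Op.GT, node.right)):
            cond = Condition(node.split_feature, op, threshold=node.split_threshold)
            new_path = path + [cond]
            if len(new_path) > depth:
                yield new_path
            yield from walk(child, new_path)

    yield from walk(root, [])


def _ensemble_depth(ensemble: TreeEnsemble) -> int:
    def depth(node: TreeNode) -> int:
        if node.is_leaf:
            return 0
        return 1 + max(depth(node.left), depth(node.right))

    return max(depth(t) for t in ensemble.trees)


def _paths_at_depth(root: TreeNode, depth: int):
    """Yield condition paths of exactly ``depth`` splits, left-first."""

    def walk(node: TreeNode, path: list[Condition]):
        if node.is_leaf:
            return
        for op, child in ((Op.LE, node.left), (Op.GT, node.right)):
            cond = Condition(node.split_feature, op, threshold=node.split_threshold)
            new_path = path + [cond]
            if len(new_path) == depth:
                yield new_path
            else:
                yield from walk(child, new_path)

    yield from walk(root, [])
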