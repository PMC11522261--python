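"""Synthetic cohorts for exercising the rule pipeline end to end.

Two generators:

* :func:`generate_cohort` draws the ten named lesion features — eight
  continuous radiomic signatures plus the binary flags "spiculated
  margin" and "pleural indentation" — from marginals calibrated so
  that every published rule threshold splits its feature's 1–99%
  range non-degenerately, then assigns IAC/MIA-AIS labels by one of
  three mechanisms (the published 15-rule logistic model, a set of
  planted rules, or a plain logistic-linear score).

* :func:`generate_radiomics_table` builds a high-dimensional
  (hundreds to ~1600 columns) correlated feature table — blocks of
  near-duplicate noise columns, near-constant columns, a handful of
  label-informative features — to stress the two-phase selection
  pipeline.

Both are fully reproducible given the seed.  The marginals emulate the
scale of a screening cohort of small (< 20 mm) pulmonary nodules; they
do not model scanner effects, feature measurement error correlations,
or the real joint distribution of radiomic signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureTable
from .rules import Rule, RuleSet, rules_to_dataset

__all__ = [
    "DEFAULT_FEATURE_SPECS",
    "CohortConfig",
    "generate_cohort",
    "generate_radiomics_table",
]

#: Marginal distributions of the ten lesion features.  Locations and
#: spreads are loosely matched to the axis-length statistics of small
#: pulmonary nodules (major axis ~8.6-11 mm) and chosen so the 1-99%
#: range of each continuous feature brackets every published rule
#: threshold on it.
DEFAULT_FEATURE_SPECS: dict[str, dict] = {
    "original_shape_MajorAxisLength": {"dist": "lognormal", "median": 9.8, "sigma": 0.25},
    "original_firstorder_10Percentile": {"dist": "normal", "loc": -700.0, "scale": 120.0},
    "original_firstorder_90Percentile": {"dist": "normal", "loc": -280.0, "scale": 170.0},
    "original_glcm_JointEntropy": {"dist": "normal", "loc": 8.8, "scale": 0.6},
    "wavelet-LLH_firstorder_Maximum": {"dist": "normal", "loc": 430.0, "scale": 160.0},
    "wavelet-LLH_glszm_LargeAreaHighGrayLevelEmphasis": {
        "dist": "lognormal", "median": 20000.0, "sigma": 1.2
    },
    "lbp-3D-k_glcm_Imc2": {"dist": "beta", "a": 1.8, "b": 10.0, "scale": 1.0},
    "lbp-3D-m1_glrlm_LongRunEmphasis": {"dist": "lognormal", "median": 26.0, "sigma": 0.45},
    "spiculated margin": {"dist": "bernoulli", "p": 0.35},
    "pleural indentation": {"dist": "bernoulli", "p": 0.40},
}


@dataclass
class CohortConfig:
    """Recipe for one synthetic cohort.

    ``label_mechanism``:

    * ``"published_model"`` — labels are Bernoulli draws from
      sigmoid(sharpness * (Y - offset)) where Y is the published
      15-rule linear predictor.  ``label_sharpness`` (default 4)
      steepens the printed equation so the oracle model discriminates
      at the level reported for the emulated study (AUC ~0.95); with
      sharpness 1 the Bernoulli draw alone would cap any model near
      AUC 0.78.  ``prevalence_target`` (default 0.23, the IAC
      fraction of the emulated cohort) shifts the offset to hit the
      desired positive rate.
    * ``"planted_rules"`` — label 1 iff any of ``planted_rules``
      fires.
    * ``"logistic_linear"`` — sigmoid of a linear score on the
      standardized continuous features with ``linear_coefs``.

    ``noise`` flips each label independently afterwards, so recovery
    difficulty is tunable separately from the mechanism.
    """

    n: int = 400
    seed: int = 0
    feature_specs: dict[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_SPECS)
    )
    label_mechanism: str = "published_model"
    noise: float = 0.0
    prevalence_target: float | None = 0.23
    label_sharpness: float = 4.0
    planted_rules: RuleSet | None = None
    linear_coefs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.label_mechanism not in (
            "published_model", "planted_rules", "logistic_linear"
        ):
            raise ValueError(f"unknown label mechanism {self.label_mechanism!r}")


def _draw(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    dist = spec["dist"]
    if dist == "lognormal":
        return rng.lognormal(np.log(spec["median"]), spec["sigma"], n)
    if dist == "normal":
        return rng.normal(spec["loc"], spec["scale"], n)
    if dist == "beta":
        return spec.get("scale", 1.0) * rng.beta(spec["a"], spec["b"], n)
    if dist == "bernoulli":
        return rng.binomial(1, spec["p"], n).astype(float)
    if dist == "mixture":  # two-component normal mixture
        comp = rng.random(n) < spec.get("w", 0.5)
        a = rng.normal(spec["loc1"], spec["scale1"], n)
        b = rng.normal(spec["loc2"], spec["scale2"], n)
        return np.where(comp, a, b)
    raise ValueError(f"unknown distribution {dist!r}")


def generate_cohort(config: CohortConfig) -> FeatureTable:
    """Draw a cohort per the config; identical tables for identical
    config + seed."""
    rng = np.random.default_rng(config.seed)
    data = {
        name: _draw(spec, config.n, rng)
        for name, spec in config.feature_specs.items()
    }
    frame = pd.DataFrame(data)
    table = FeatureTable(frame)

    if config.label_mechanism == "published_model":
        from .diagnostic import linear_predictor, published_model

        model = published_model()
        ind = rules_to_dataset(model.ruleset, table)
        y_lin = linear_predictor(model, ind)
        offset = 0.0
        if config.prevalence_target is not None:
            offset = _solve_offset(
                y_lin, config.label_sharpness, config.prevalence_target
            )
        p = 1.0 / (1.0 + np.exp(-config.label_sharpness * (y_lin - offset)))
        labels = rng.binomial(1, p)
    elif config.label_mechanism == "planted_rules":
        if config.planted_rules is None or len(config.planted_rules) == 0:
            raise ValueError("planted_rules mechanism needs a non-empty ruleset")
        ind = rules_to_dataset(config.planted_rules, table)
        labels = (ind.to_numpy().any(axis=1)).astype(int)
    else:  # logistic_linear
        if not config.linear_coefs:
            raise ValueError("logistic_linear mechanism needs linear_coefs")
        z = np.zeros(config.n)
        for feat, c in config.linear_coefs.items():
            v = frame[feat].to_numpy(dtype=float)
            sd = v.std()
            z += c * (v - v.mean()) / (sd if sd > 0 else 1.0)
        labels = rng.binomial(1, 1.0 / (1.0 + np.exp(-z)))

    if config.noise > 0:
        flips = rng.random(config.n) < config.noise
        labels = np.where(flips, 1 - labels, labels)
    table.labels = pd.Series(labels, index=frame.index).astype(int)
    return table


def _solve_offset(y_lin: np.ndarray, sharpness: float, target: float) -> float:
    """Bisection for the offset making mean sigmoid probability hit the
    target prevalence."""
    lo, hi = y_lin.min() - 10.0, y_lin.max() + 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = (1.0 / (1.0 + np.exp(-sharpness * (y_lin - mid)))).mean()
        if p > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_radiomics_table(
    n: int = 300,
    p: int = 500,
    n_informative: int = 5,
    n_blocks: int = 10,
    block_size: int = 5,
    n_near_constant: int = 10,
    effect_size: float = 1.0,
    prevalence: float = 0.4,
    seed: int = 0,
) -> tuple[FeatureTable, list[str], list[list[str]]]:
    """High-dimensional correlated table stressing the selection pipeline.

    Columns: ``n_informative`` standalone features shifted by
    ``effect_size`` standard deviations between classes (named
    ``informative_*``); ``n_blocks`` blocks of ``block_size``
    rank-identical noise columns (a shared base plus strictly monotone
    distortions, within-block Spearman ~1, named ``block<i>_f<j>``);
    ``n_near_constant`` almost-constant columns; independent noise
    columns padding up to ``p``.  Returns the labelled table, the
    informative feature names, and the block memberships.
    """
    if p < n_informative + n_blocks * block_size + n_near_constant:
        raise ValueError("p too small for the requested structure")
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, prevalence, n)
    cols: dict[str, np.ndarray] = {}

    informative = []
    for i in range(n_informative):
        name = f"informative_{i}"
        cols[name] = effect_size * y + rng.normal(0.0, 1.0, n)
        informative.append(name)

    blocks: list[list[str]] = []
    for b in range(n_blocks):
        base = rng.normal(0.0, 1.0, n)
        members = []
        for j in range(block_size):
            name = f"block{b}_f{j}"
            # strictly monotone distortion keeps Spearman rho at 1
            cols[name] = (j + 1.0) * base + 0.1 * j * base**3
            members.append(name)
        blocks.append(members)

    for i in range(n_near_constant):
        v = np.full(n, 5.0)
        v[rng.integers(0, n)] += 1e-9
        cols[f"nearconst_{i}"] = v

    n_noise = p - len(cols)
    for i in range(n_noise):
        cols[f"noise_{i}"] = rng.normal(0.0, 1.0, n)

    frame = pd.DataFrame(cols)
    kinds = {c: "continuous" for c in frame.columns}
    table = FeatureTable(frame, labels=pd.Series(y), kinds=kinds)
    return table, informative, blocks


#: Marginals for the planted-rule recovery cohort.  The four features
#: carrying planted thresholds are two-component mixtures — emulating
#: the group separation visible in real nodule cohorts (major axis
#: ~8.6 mm in MIA/AIS vs ~11 mm in IAC) — with each planted threshold
#: placed in the low-density gap between modes.  A rule-recovery
#: benchmark needs identifiable boundaries: when the data are dense at
#: a boundary, every learner's threshold estimate carries irreducible
#: jitter and no method can match the planted region closely.
PLANTED_FEATURE_SPECS: dict[str, dict] = {
    **DEFAULT_FEATURE_SPECS,
    "original_shape_MajorAxisLength": {
        "dist": "mixture", "w": 0.55,
        "loc1": 8.6, "scale1": 1.2, "loc2": 13.0, "scale2": 1.3,
    },
    "original_glcm_JointEntropy": {
        "dist": "mixture", "w": 0.6,
        "loc1": 8.2, "scale1": 0.35, "loc2": 9.6, "scale2": 0.35,
    },
    "wavelet-LLH_firstorder_Maximum": {
        "dist": "mixture", "w": 0.55,
        "loc1": 300.0, "scale1": 70.0, "loc2": 550.0, "scale2": 80.0,
    },
    "original_firstorder_10Percentile": {
        "dist": "mixture", "w": 0.45,
        "loc1": -790.0, "scale1": 55.0, "loc2": -540.0, "scale2": 60.0,
    },
}


def planted_threshold_rules() -> RuleSet:
    """Three planted rules for recovery experiments.

    All three are two-condition conjunctions.  This is deliberate: the
    complement of a union of single conditions is itself one
    conjunction, so a sparsity-driven selector can legitimately
    represent such labels with a single complement rule and the
    planted set is not identifiable.  With two-condition components
    the union is the minimal conjunctive-rule representation of its
    own decision function.  Thresholds sit in the low-density gaps of
    :data:`PLANTED_FEATURE_SPECS`.
    """
    from .rules import parse_rule

    texts = {
        "planted_size": (
            "original_shape_MajorAxisLength > 11.2 & "
            "original_firstorder_10Percentile <= -660"
        ),
        "planted_entropy": (
            "original_glcm_JointEntropy > 8.9 & "
            "wavelet-LLH_firstorder_Maximum > 430"
        ),
        "planted_flags": "spiculated margin & pleural indentation = 1",
    }
    return RuleSet([parse_rule(t, id=k) for k, t in texts.items()])


def planted_cohort_config(
    n: int = 400, seed: int = 0, noise: float = 0.05
) -> CohortConfig:
    """Standard configuration of the planted-rule recovery study."""
    return CohortConfig(
        n=n,
        seed=seed,
        noise=noise,
        label_mechanism="planted_rules",
        planted_rules=planted_threshold_rules(),
        feature_specs=dict(PLANTED_FEATURE_SPECS),
    )
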