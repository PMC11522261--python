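# rulefuse

Interpretable rule-ensemble diagnostic modelling for radiomics.

Clinicians reading CT scans of small pulmonary nodules need to judge
whether a lesion is an invasive adenocarcinoma (IAC) or a less
aggressive subtype (MIA/AIS) — a decision that changes treatment.
Black-box classifiers on radiomic features discriminate well but give
no account of *why*.  `rulefuse` builds the alternative: a risk model
made of short, readable decision rules
("`original_shape_MajorAxisLength > 9.93 & wavelet-LLH_firstorder_Maximum > 511.67`"),
harvested from tree ensembles, fused through a sparse linear model,
and assembled into an ordinary logistic equation a radiologist can
read line by line.

It is aimed at biostatisticians and imaging researchers who work with
tabular radiomic feature matrices (samples × named features, binary
outcome) and want rule-based models with a full audit trail of how
every rule was generated, filtered, and weighted.

## The model

Decision rules are conjunctions of axis-aligned conditions; rule k is
an indicator r_k(x) ∈ {0, 1}.  Candidate rules are the root-to-node
paths of three tree ensembles with different weighting semantics —
gradient boosting and AdaBoost (stagewise-weighted, sequentially
correlated trees, F_m(x) = F_{m−1}(x) + β_m h(x; r_m)) and a random
forest (equal independent trees, F(x) = (1/M) Σ h_m(x; r_m)).

Rules and winsorized linear terms of the original features enter a
sparse linear model fitted with an L1 penalty,

    f̂(x) = β̂₀ + Σ_k α̂_k r_k(x) + Σ_j β̂_j l_j(x_j),

minimizing Σ_i L(y⁽ⁱ⁾, f(x⁽ⁱ⁾)) + λ (Σ|α_k| + Σ|β_j|) with binomial
deviance L.  A rule's importance is |α̂_k|·√(s_k(1−s_k)) with s_k its
support.  The selection cascade — per-source importance (> 0.1) and
outcome-correlation (|φ| > 0.4) filters, provenance-aware merge, an
L1 subset selection, and an exact linear-SHAP contribution screen —
reduces hundreds of candidates to a handful, over which a final
multivariate logistic model

    Y = β₀ + Σ_k c_k · Rule_k,   P(IAC) = 1 / (1 + e^(−Y))

is fitted and reported as an equation plus rule table.  The published
15-rule lung-adenocarcinoma model ships as a fixture
(`rulefuse.published_model()`), and a synthetic-cohort generator
stands in for the study data so every stage is testable offline.

Feature selection from ~1600 radiomic signatures is included as a
two-phase pipeline: variance filter → Spearman pruning (|ρ| > 0.9) →
mRMR top-100 → repeated-LASSO stability selection down to ~10 key
features.

## Worked example

Score the packaged 20-lesion example cohort with the published 15-rule
model:

```python
from importlib import resources
import numpy as np
from rulefuse import published_model, rules_to_dataset, linear_predictor
from rulefuse.features import FeatureTable

path = resources.files("rulefuse.data") / "worked_example_cohort.csv"
with resources.as_file(path) as p:
    cohort = FeatureTable.read_csv(p)

model = published_model()
ind = rules_to_dataset(model.ruleset, cohort)   # 20 x 15 indicator matrix
Y = linear_predictor(model, ind)
proba = 1 / (1 + np.exp(-Y))
```

The first lesions print as:

```
lesion  rules firing                     Y       P(IAC)
     0  -                             -0.3265  0.419
     1  Rule5,Rule6,Rule7,Rule14,Rule15 +1.2106  0.770
     2  Rule7,Rule15                  +0.5059  0.624
     3  Rule8,Rule11,Rule14,Rule15    +0.7161  0.672
     4  Rule5,Rule12,Rule13           +0.5388  0.632
     5  Rule1,Rule5,Rule15            -0.9616  0.277
```

Lesion 0 fires no rule, so its linear predictor is the model
intercept −0.3265 (baseline odds of invasiveness).  Lesion 1 fires
five risk-raising rules (spiculated margin among them) and its IAC
probability rises to 0.77; lesion 5 fires the strongly protective
Rule1 (small, low-attenuation lesion) and drops to 0.28.

The same workflow runs from the shell:

```
rulefuse simulate --mechanism published_model --n 400 --seed 7 --out cohort.csv
rulefuse run-all --input cohort.csv --test-fraction 0.33 --seed 7 --outdir run/
```

which writes the selected features, candidate and final rule sets, a
per-rule selection trace, the model card (equation + rule table), the
evaluation report (AUC with DeLong CI, accuracy/precision/recall/F1,
ROC points), and a manifest that makes the run reproducible
bit-for-bit.

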