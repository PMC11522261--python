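# Methods

`rulefuse` implements an interpretable diagnostic-modelling workflow for
binary outcomes on tabular radiomic features, developed around the
problem of discriminating invasive lung adenocarcinoma (IAC) from
minimally invasive disease (MIA/AIS) in small pulmonary nodules.  The
workflow has four stages: two-phase feature selection, rule generation
from three tree-ensemble architectures, sparse linear fusion and
selection of the rules, and a final multivariate logistic model over
rule indicators.  This note records the model, the parameters that
matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The rule language

A *rule* r(x) is a conjunction of axis-aligned conditions — `f <= t`,
`f > t`, `f ∈ (l, u]`, or flag equality on a binary feature — that
evaluates to 1 when every condition holds.  Boundary semantics follow
binary-tree splits: `<=` inclusive, `>` strict, intervals left-open and
right-closed.  Canonicalization intersects repeated conditions on one
feature (LE thresholds to their minimum, GT to their maximum, a
coexisting pair to an interval), rejects contradictions, and sorts
conditions by feature name, so rules harvested from different tree
paths compare structurally.  The parser accepts the textual dialect
used in clinical rule tables, including thousands separators, Unicode
minus signs, and ensemble-provenance prefixes (`gbc_`, `rf_`, `ada_`)
which are stripped into provenance metadata.

Rule *support* s is the firing fraction on a table.  A fitted rule
term's *importance* is |alpha| * sqrt(s(1-s)) — coefficient magnitude
times the indicator's standard deviation — and a linear term's is
|beta| * sd(l); the definition follows the original rule-ensemble
literature and makes rule and linear terms comparable.

`prune_conditions` reduces a rule to a minimal sufficient conjunction:
conditions whose removal changes the indicator on less than
`min_effect` (default 0.05) of samples are dropped, least-binding
first.  Such conditions are artefacts of the particular tree path a
rule was harvested from; pruning collapses families of path variants
onto their common core and materially improves the stability of the
downstream selection.

## Two-phase feature selection

Phase 1 operates on the continuous radiomic signatures:

1. **Variance filter** on the raw (pre-scaling) columns, tolerance
   1e-8 — scaling first would renormalize every non-constant column to
   unit variance and make the filter vacuous.
2. **Scaling normalization** to zero mean, unit (population) variance.
3. **Spearman pruning** at |rho| > 0.9: pairs are visited in
   decreasing |rho|; within a pair the feature with the larger mean
   absolute correlation to all remaining features is dropped (ties go
   to the lexicographically later name) until no pair exceeds the
   cutoff.  Spearman is used because monotone transforms of the same
   underlying signal should count as redundant.
4. **mRMR** (difference form): greedy ranking maximizing I(f; y) minus
   the mean mutual information with already-selected features, with
   continuous features discretized into 10 equal-frequency bins; the
   top 100 survive by default.

Phase 2 merges the shortlist with the binary radiological flags (which
bypass phase 1) and applies **stability selection**: repeated
L1-penalized logistic fits, each with re-randomized stratified
cross-validation folds and the one-standard-error penalty, recording
per-feature selection frequency.  Features selected in at least half
the repeats are kept, ordered by frequency and truncated to
`max_features` (default 10).  The repeat count defaults to 500;
the packaged experiments use 20 repeats at n=300, which already
separates planted signal (frequency 1.0) from noise (mostly 0) — the
full 500 is a production setting, not a statistical necessity at these
problem sizes.  Because only folds are re-randomized (the data are
fixed), a noise feature with a lucky in-sample correlation can recur
across repeats; subsampling-based stability selection would trade this
for extra variance.

## Rule generation

Three ensembles are fitted with the reference configuration: gradient
boosting (500 trees, depth 5, learning rate 0.1), random forest (500
trees, minimum leaf size 1), and discrete (SAMME) AdaBoost (30 depth-5
trees).  Gradient boosting and AdaBoost produce weighted, sequentially
correlated trees (per-tree weights: the learning rate, and the SAMME
log-odds stage weights); the forest's trees are equal and independent
(weights 1/M).  Every root-to-node path of every tree is a candidate
rule; a tree with N nodes yields N-1 candidates of length 1 up to its
depth, and left/right branches map to `<=` / `>`.

Whole ensembles hold far more candidates than are useful (a forest
with unit leaves on 400 samples holds ~400k paths), so the two
RuleFit-fused methods are reduced to a *rule budget* (default 80) by
screened extraction: enumerate all distinct non-degenerate rules of
length <= 2 from every tree plus deeper paths up to a cap, rank by
|phi| correlation with the outcome, and keep greedily while skipping
candidates whose indicator overlaps an already-kept rule at Jaccard
>= 0.95.  The redundancy control matters: boosted ensembles contain
hundreds of threshold-jittered copies of their strongest split, and
without it the budget holds one signal many times rather than many
signals once.  Kept rules are condition-pruned and deduplicated.  The
AdaBoost pool is not budget-capped; all its extracted rules (pruned
and deduplicated) go to the correlation filter, mirroring the
asymmetric treatment of the sources in the emulated workflow.

## Sparse linear fusion and the selection cascade

For gradient boosting and random forest, rule indicators and linear
terms of the original features enter a joint L1-penalized logistic
model.  Continuous features are winsorized at the 2.5%/97.5% quantiles
and standardized; binary flags pass through.  The penalty path starts
at the smallest lambda that zeroes every coefficient and descends
geometrically (30 points, ratio 1e-3); lambda is chosen by stratified
5-fold cross-validated binomial deviance with the one-standard-error
rule.  The intercept is unpenalized: liblinear's internal intercept
handling penalizes it, so after each solve the intercept is re-fitted
alone by one-dimensional Newton iteration with the coefficients fixed
(this also makes the large-lambda null model's intercept equal the
log-odds of prevalence to machine precision).  Rules with importance
strictly greater than 0.1 survive.

AdaBoost rules are filtered by outcome correlation instead: the phi
coefficient (Pearson correlation of binary vectors) must exceed 0.4 in
absolute value.  Constant indicators get phi 0 by convention.

The surviving per-method rule datasets are merged column-wise;
duplicate rules (identical canonical condition sets) collapse to one
column with the union of source provenances.  An L1 logistic fit on
the merged indicators selects the rule subset.  The penalty for this
stage is chosen by the **extended BIC** (gamma = 1) along the path
rather than by cross-validated deviance: the object of interest here
is the active set itself, and CV deviance systematically prefers
dense, noise-fitting supports in which clean single-signal rules are
displaced by finer partitions of the same regions.  EBIC selects the
minimal subset whose fit justifies its size, matching the workflow's
stated goal of a minimum number of explainable rules; `cv_min` and
`cv_1se` remain available.

Finally, a multivariate logistic model is refitted on the selected
support (relaxed-LASSO style — L1-shrunk weights systematically
understate effect sizes) and each rule's SHAP contribution is
computed.  For a model linear in the indicators the Shapley value is
exact and closed-form: phi_ij = w_j (x_ij - mean_i x_ij), which the
tests verify against brute-force permutation Shapley.  A rule's
contribution is its mean |phi| over samples, measured on the log-odds
scale.  The published threshold "0.5" is dimensionally ambiguous, so
the filter offers three modes: `raw` (0.5 log-odds), `normalized`
(0.5 of the largest contribution), and the default `auto`, which keeps
a rule passing either reading.  The union behaves like `raw` on
sharply discriminative models and like `normalized` on models whose
coefficients are uniformly small; a 6-seed stability study on the
synthetic cohorts showed each single reading deleting whole signals on
the cohort type it mismatches.  If the filter would empty the
selection entirely, the LASSO support is kept instead, with a logged
warning.

## Diagnostic model and evaluation

The final model is an ordinary multivariate logistic regression over
the selected rule indicators.  Constant columns are excluded from the
fit and given zero coefficients.  On perfect separation or
non-convergence — easy to reach with binary designs at small n — the
model is refitted with a small ridge penalty (1e-6) and a warning.
AUC is computed by the tie-corrected rank (Mann-Whitney) statistic;
its confidence interval by DeLong's structural-components method
(default, deterministic) or a stratified bootstrap.  Threshold metrics
(accuracy, precision, recall, F1) come from the confusion matrix at
probability 0.5, or at the Youden-optimal ROC point on request.  The
model exports as a human-readable card — the signed-coefficient
equation plus the rule table — with an embedded machine-readable block
that round-trips exactly.

The published 15-rule IAC model ships as a fixture: the rule table in
its original dialect and the printed equation's coefficients
(intercept -0.3265; Rule1 -0.7705 ... Rule15 +0.3891).  The packaged
worked example (20 synthetic lesions with their indicator matrix and
linear predictors) is generated by this code and frozen for
regression testing.

## Synthetic cohorts

`generate_cohort` draws the ten lesion features from marginals chosen
so every published rule threshold splits its feature's 1–99% range
non-degenerately, with locations and spreads loosely matched to
small-nodule cohorts (major axis log-normal around 9.8 mm).  Labels
come from one of three mechanisms:

* **published_model** — Bernoulli draws from
  sigmoid(sharpness * (Y - offset)), Y the published linear predictor.
  Sharpness defaults to 4, set so the oracle model's discrimination
  matches the emulated study's reported level (AUC ~0.95 at large n);
  with sharpness 1 the Bernoulli noise alone would cap every model
  near AUC 0.78.  The offset targets prevalence 0.23, the IAC fraction
  of the emulated cohort.
* **planted_rules** — label 1 iff any planted rule fires, then
  independent label flips with probability `noise`.
* **logistic_linear** — sigmoid of a linear score on standardized
  features.

The planted-rule recovery study uses its own marginals
(`PLANTED_FEATURE_SPECS`): the four features carrying planted
thresholds are two-component mixtures with each threshold in the
low-density gap between modes, and all three planted rules are
two-condition conjunctions.  Both choices are identifiability
requirements, not conveniences: thresholds in dense regions carry
irreducible estimation jitter that caps the attainable
indicator-Jaccard below any strict recovery target, and a union of
*single*-condition rules is not identifiable at all — its complement
is itself one conjunction, so a sparsity-driven selector can
legitimately represent the labels with a single complement rule.
Bimodality also mirrors the real cohort's group separation in lesion
size (major axis ~8.6 mm in MIA/AIS vs ~11 mm in IAC).

`generate_radiomics_table` builds the high-dimensional stress input
for feature selection: standalone label-informative features (class
shift 1 sd by default), blocks of rank-identical noise columns (a
shared base under strictly monotone distortions, within-block Spearman
~1), near-constant columns for the variance filter, and independent
noise padding to the requested width.

What these cohorts do **not** emulate: scanner- or site-specific
effects, measurement-error correlation between radiomic features, the
real joint distribution of signatures (features are drawn
independently), or class-dependent feature distributions beyond what
the label mechanism induces.  Passing the synthetic studies therefore
demonstrates the machinery's correctness and the conditions under
which the methodology can work — not clinical performance.

## Known limitations

* Rule selection under near-collinearity is set-valued: many rule
  subsets represent the same decision function almost equally well
  (threshold-jittered copies, region partitions, partial complements),
  and which representative survives the L1 stage is not stable across
  resampling.  The selection traces exist precisely so users can see
  the competing rules and their statistics.
* The end-to-end synthetic study shows a structural tension in the
  emulated workflow itself: when labels follow the published equation,
  the published rules' marginal correlations with the outcome are far
  below the workflow's own correlation threshold (median |phi| ~0.22
  vs a 0.4 gate, at any label sharpness), so the cascade retains only
  a fraction of the generating signal and its held-out AUC
  (~0.68-0.75) sits well below the oracle refit (~0.87 under the same
  split and noise).  With real cohorts, where rules are selected on
  the same data that generated them, this bound does not apply.
* The repeated-LASSO stage randomizes folds only; see above.
* DeLong intervals are asymptotic; at very small n or AUC near 1 the
  bootstrap option is more honest.
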