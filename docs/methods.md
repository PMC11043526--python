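# Methods

## The model

`enumstack` builds two-layer stacking ensembles for K-class classification
of expression profiles. Layer one is a set of probability-emitting
classifiers fitted on the gene features; layer two is a single classifier
fitted on the concatenated class-probability vectors of a subset of layer-one
models. The package's contribution is the *catalogue*: rather than choosing
one stack, it enumerates every subset of size ≥ 2 of the selected base
models, crosses each with every registered meta-learning algorithm, and
ranks the resulting models (together with the tuned single base models) by a
multi-metric score on held-out cohorts. With five selected base models and
nine meta algorithms the catalogue has `9·Σ_{k=2}^{5} C(5,k) = 234` stacked
entries and 243 entries in total; the general cardinality law
`M·Σ_{k=2}^{B} C(B,k)` is enforced by construction and property-tested.

Assumptions: features are already normalized, roughly Gaussian per class
(log2-TPM-like); cohorts share a feature universe and class set; classes
are assigned one per sample (no mixed or unknown labels).

## Evaluation metrics

Eleven metrics per (model, cohort): accuracy, balanced accuracy, F1, NPV,
PPV, PR-AUC, precision, recall, ROC-AUC, sensitivity, specificity. All
per-class quantities use one-vs-rest framing with **macro** (unweighted)
averaging, chosen for class-imbalance robustness and consistency with the
macro-averaged AUC; no micro/weighted modes are offered. `precision`/`recall`
duplicate `ppv`/`sensitivity` by definition and are retained so a report
always carries exactly the conventional 11 names. ROC-AUC is the rank
statistic (ties 0.5); PR-AUC is average precision (step-wise summation, not
trapezoidal interpolation, avoiding the optimistic bias of interpolated PR
curves). Numerical conventions, fixed for bit-reproducibility:

* argmax ties in label assignment go to the lexicographically first class;
* a per-class metric with zero denominator is defined as 0 (logged);
* a class absent from the true labels, or degenerate for an AUC, is dropped
  from the macro mean (logged); if every class is degenerate the AUC errors.

The catalogue rank score (*mean metric*) is the grand mean of the 11 metrics
across all test cohorts, i.e. the flat mean of `11·N` values; ties in the
ranking break by model name.

## Hyperparameter tuning

A sequential model-based optimizer: `min(5, budget)` random warm-start
points, then a Gaussian-process surrogate (Matérn 5/2, normalized outputs)
with expected improvement maximized over a candidate pool (96 random draws,
or the full grid when the space is discrete and ≤ 1024 points). Defaults
follow the framework's protocol: at most **50** evaluations, early stop
after **10** consecutive evaluations without strict improvement, objective
**balanced accuracy**. Base models are tuned under 5-fold stratified CV;
meta-learners under bootstrap resampling with **10** resamples scored
out-of-bag. Resampling plans are frozen per tuning run so every candidate
sees identical splits; evaluations that raise are scored −∞ and the search
continues; fully discrete spaces are never re-evaluated at a point, and an
exhausted space terminates the search. Everything is deterministic under a
fixed seed: a single global seed fans out to components through a SHA-256
hash of a component label path (`util.derive_seed`).

Per-algorithm default search spaces (package choices, overridable per run):
elastic net mixing α∈[0,1], penalty λ∈[1e-4,10] log; RF trees 100–1000, max
feature fraction 0.1–1; XGBoost/LightGBM depth 2–8, learning rate
[1e-3,0.3] log, trees 50–500; KNN k 3–25; MLP one hidden layer 8–128 units,
L2 [1e-5,1e-1] log; SVM C [1e-2,1e2] log, RBF γ [1e-4,1] log; decision tree
depth 2–12; logistic regression C [1e-2,1e2] log. Multinomial logistic
regression and elastic net are distinct registry entries (ridge-default vs
tuned elastic penalty). SVM probabilities use the backend's built-in Platt
calibration. All backends run single-threaded with seeded randomness.
`compact_search_spaces()` narrows ensemble sizes (RF 50–150 trees,
XGBoost/LightGBM 30–100 rounds, MLP 8–32 units) for cohorts of a few
hundred samples, where larger ensembles only add runtime.

## Leakage control in stacking

Meta-learners train on **out-of-fold** base probabilities: each training
sample's probability row comes from a base model fitted with that sample's
fold held out (same fold plan as the CV objective under the same seed), so
the second layer cannot learn base-model overfit. At prediction time base
probabilities come from base models refitted on the full training cohort —
the standard stacking deployment split between meta-training inputs and
serving inputs. All K probability columns are kept per member; penalized
meta-learners handle the resulting redundancy (rows sum to one), and
dropping a column would break the meta-feature definition.

## Feature selection

Two selectors over the training cohort, combined by union (default; the
two methods screen at different levels, so pooling preserves both views) or
intersection:

* **SVM-RFE**: refit a linear one-vs-rest SVM each round, score features by
  the sum over class weight vectors of squared coefficients, drop the
  weakest `step` (count or fraction), stop at `target_size`.
* **RF backward elimination** (varSelRF-style defaults): permutation
  importances computed **once** on the full forest (re-ranking each round
  would bias selection), drop the bottom `max(1, round(0.2·current))`
  features per round down to 2, record out-of-bag error per size, and pick
  the smallest set whose OOB error is within `sd_tolerance` (default 1)
  binomial standard errors of the minimum.

## Shapley attributions

Model-agnostic permutation-sampling Shapley values on the probability scale
per class, with the coalition value `v(S) = E_background[f(x_S, b_~S)]`
(mean-imputation over a background table — by default the training cohort
subsampled to ≤ 100 rows, seeded). The estimator enumerates all `F!`
permutations when the budget covers them (making it exact) and caches
coalition values, so cost is bounded by distinct coalitions (≤ 2^F). Local
accuracy holds by telescoping within each permutation; a final residual
redistribution absorbs floating-point drift. An exact `2^F` enumeration
oracle (≤ 12 features) backs the tests for the dummy, symmetry and
efficiency axioms. The model-agnostic estimator was chosen over
tree-specific algorithms because the explained object is the composite
two-layer pipeline in original feature space. Per-class importance is the
mean |SHAP| over explained samples; dependence records (feature value vs
SHAP value) are exported for plotting rather than rendered.

## Synthetic data generator

Each cohort draws labels by multinomial sampling from the class proportions
(uniform default), then gene values from N(0,1); the informative genes are
split into K contiguous blocks and class k's mean is shifted by
`effect_size` on block k, so all classes are mutually separable once the
effect is large; a per-cohort scalar batch offset may be added to all
values. The fixed `worked_fixture()` (12 samples × 6 features, exactly 4
per class) anchors exact metric and shape assertions. What the generator
does **not** emulate: count-level noise and library-size effects, gene–gene
correlation structure, heavy-tailed expression, label noise, and realistic
batch effects (the offset is a scalar, not gene-specific). Passing tests
therefore demonstrate the correctness and internal consistency of the
framework's machinery, not clinical-grade subtype accuracy on real cohorts.

## Demonstration scale

End-to-end demonstrations (the acceptance script and the heavy test) use a
300-sample training cohort, two 100-sample test cohorts, 30 genes with 9
informative at effect size 2 — sizes comparable to the cohorts this kind of
classifier is built for — with the bootstrap ×10 protocol but a reduced
SMBO budget (6 evaluations for base models, 4 for meta-learners) and the
compact search spaces: tuning 243 models at the full 50-evaluation budget
adds nothing to a demonstration on synthetic data beyond runtime. Library
defaults remain 50/10/×10.

## Known limitations

* The SMBO surrogate treats integer and categorical dimensions by
  encoding/rounding; very small budgets reduce it to random search.
* Per-algorithm search spaces are pragmatic defaults, not tuned per study.
* Backend nondeterminism: all registered backends are seeded and
  single-threaded; any future backend without a seed must be flagged in the
  bundle manifest.
* The catalogue refits one meta-learner per (combination, meta) pair;
  runtime grows as `M·2^B`, so B beyond ~8 selected base models is
  impractical.
* Bundles serialize fitted backends with joblib; they are loadable only
  under compatible library versions (the manifest records the schema
  version and rejects mismatches).
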