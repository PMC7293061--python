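# Methods

## Problem and model

`stressecho` predicts the outcome of a stress echocardiogram (positive =
inducible ischaemia, i.e. new regional wall-motion abnormalities under
dobutamine stress) from minimal clinical variables: 13 binary risk factors and
medications, a three-level smoking status, and continuous age and weight.  The
pipeline has four stages:

1. **Cohort** — a patient-by-variable table with a binary outcome.  The
   reference cohort (529 patients, 82 positive / 447 negative) is not publicly
   available, so the package ships a generator that reproduces its published
   class-conditional structure (see below).
2. **Encoding** — binary variables pass through as 0/1; smoking is ordinally
   coded nonsmoker=0, ex-smoker=1, smoker=2; age and weight are min-max
   normalized, `(x − min)/(max − min)`, then cut into 10 equal-width bins
   indexed 1..10.  Feature selection on discrete estimates is biased toward
   continuous features, hence the discretization.
3. **Feature ranking** — joint mutual information maximization (JMIM).  The
   first feature maximizes the individual mutual information I(f; C) with the
   class C; each subsequent step selects the candidate f_i maximizing
   min_{f_s ∈ S} I(f_i, f_s; C) over the already-selected set S, where the
   pair (f_i, f_s) is treated as a single variable on the product alphabet.
   The max-of-min criterion scores a candidate by its *worst* pairing, so it
   favours features that complement everything already chosen rather than
   features that are individually strong but redundant.  `mim_rank` (a plain
   sort by individual MI) is provided as the interaction-blind baseline.
4. **Classification** — SVM (RBF kernel) or random forest with the minority
   class up-weighted 4:1, evaluated by 5-fold cross-validation.  The
   classifier is retrained after adding each feature in rank order, producing
   accuracy/sensitivity/specificity curves over the subset size k.

## Estimation and numerical choices

* All information quantities are plug-in (maximum-likelihood) estimates from
  contingency counts, in bits (log base 2).  The base only rescales criterion
  values and never changes an ordering.  No smoothing is applied: the intended
  regime is hundreds of patients and alphabets of at most 10 × 3 × 2 cells.
* MI is computed as H(F) + H(C) − H(F,C) and clamped at zero against
  floating-point negatives; the test oracle recomputes it with the direct
  Σ p log p/(pq) sum, and the two routes agree to 1e-12.
* Discretization bins are left-closed, right-open with the final bin
  right-closed, so the observed maximum lands in bin 10; out-of-range values
  clamp to the end bins, and a constant feature (width 0) maps everywhere to
  bin 1 and is logged.
* Argmax ties in the greedy search break toward the lowest column index.  Two
  criterion values closer than 1e-9 bits are treated as tied: mathematically
  equal scores computed along different float paths can differ in the last
  ulp, while genuinely distinct plug-in estimates at these sample sizes differ
  by far more.  Ties are logged.
* Cross-validation folds are stratified by default.  With only ~15% positives,
  purely random 5-fold splits can leave a test fold with almost no positive
  cases, making sensitivity undefined-prone; `--cv-strategy random` restores
  the literal random protocol.
* The encoder and the feature ranking are fitted on the whole dataset before
  cross-validation (the protocol this package reproduces, which values ranking
  stability over leakage-free error estimates).  For leakage-free estimates,
  refit `CohortEncoder` and `JMIMSelector` inside each training fold; the
  estimators are fold-agnostic objects, so this is a composition choice, not a
  code change.
* "Best trade-off between sensitivity and specificity" is operationalized as
  the subset size maximizing min(sensitivity, specificity) of the
  fold-averaged metrics, ties broken toward fewer features.
* Metrics are reported both fold-averaged (with the across-fold standard error
  of the mean, ddof = 1) and recomputed from the pooled confusion counts; with
  near-equal fold sizes the two agree closely, and tests require agreement
  within 0.02.
* Class weighting multiplies the minority class's misclassification cost; the
  minority class is determined from the training labels at fit time.  The 4:1
  default mirrors the roughly 4:1 negative:positive imbalance.  The same ratio
  is applied to both classifier families.
* Classifier defaults: SVC with RBF kernel, C = 1, `gamma="scale"`; random
  forest with 500 trees.  Both are seed-controlled; hyperparameters are
  exposed via `ClassifierSpec.hyperparameters` and no search is performed.

## The synthetic cohort generator

`default_cohort_spec` encodes the published class-conditional summary of the
reference cohort: for each binary variable the prevalence count/class-size per
outcome class (e.g. P(male | positive) = 61/82), the three smoking-level
proportions, and mean (SD) for age (years) and weight (kg).  The `full` spec
has class sizes (82, 447); the `no_prior_cad` spec describes the 406-patient
subset without prior coronary artery disease, class sizes (42, 364), and has
no prior-CAD variable.  In the subset table's negative class the three printed
smoking counts sum to 305 rather than 364 (an inconsistency in the source
table); the vector is renormalized over its own total.

`generate_cohort` assigns outcome labels deterministically (exact class
counts, order shuffled by the seed) and draws every variable independently
given the class: binary via Bernoulli, smoking via the categorical vector, age
and weight as Gaussians truncated below at physiological floors (18 years,
30 kg).  What this emulates: the class-conditional marginals, the class
imbalance, and the mixed variable types.  What it does not: any correlation
between variables within a class (only marginals are published, so, e.g., the
statin–hypercholesterolemia association in real patients is absent), outcome
noise conditional on covariate combinations, and any site- or time-specific
structure.  Tests passing on these cohorts therefore validate the machinery
and its statistical behaviour under the published marginals, not clinical
performance on real patients; the reference study's headline accuracies are
not reproducible without its records.

`generate_planted_cohort` builds validation cohorts with known ground truth:
informative binary features at class-conditional prevalences 0.5 ± gap/2 and
pure-noise features at 0.5 in both classes.  Defaults used throughout the
tests: 2 informative and 8 noise features, prevalence gap 0.5, 500 patients
per class for ranking recovery; 60 positive / 340 negative (15% positive) for
the class-weighting studies — sizes chosen to match the reference cohort's
scale and imbalance.

## Problem sizes used by the test and acceptance runs

Oracle equivalence uses 100 random matrices with 3–6 features and 10–40 rows
(the brute-force oracle is exponential in spirit and capped at 8 features);
ranking recovery uses 100 planted cohorts of 1,000 rows; the weighting
comparison uses 25 paired seeds of 400-row imbalanced cohorts with full 5-fold
CV at ratios 1:1 and 4:1; generator fidelity draws 10,000 patients per class
and checks every class-conditional prevalence against its 99.9% binomial CI.

## Known limitations

* Conditional independence given class is a simplification (above); rankings
  on generated cohorts reflect marginal effect sizes, not the interaction
  structure of the real data.
* Plug-in MI is biased upward at small n; with 16 features and ~500 patients
  the bias is shared across candidates and rarely reorders them, but criterion
  *values* should not be read as unbiased information estimates.
* Whole-dataset feature selection leaks label information into the CV
  estimates; the reported curves are therefore optimistic as estimates of
  out-of-sample performance (the trade-off is discussed above).
* The equal-width discretizer is sensitive to outliers through the observed
  min/max; no outlier handling is applied.
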