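# stressecho

Predicting stress-echocardiography outcome from minimal clinical variables.

Stress echocardiography detects inducible myocardial ischaemia (a marker of
significant coronary artery disease) as new regional wall-motion abnormalities
under dobutamine or exercise stress.  `stressecho` asks how far a handful of
variables already known *before* the test — sex, age, weight, risk factors
such as hypertension, diabetes, smoking status and prior CAD, and prescribed
cardiac medication — can predict that outcome, for researchers studying
clinical prioritization of echo referrals.

The pipeline:

* **Synthetic cohorts.** The reference cohort (529 patients, 82 positive /
  447 negative) is not publicly available; `default_cohort_spec` encodes its
  published class-conditional summary (per-class prevalences, smoking
  proportions, age/weight mean ± SD) and `generate_cohort` draws cohorts with
  exactly that structure.  `generate_planted_cohort` builds cohorts with known
  informative vs pure-noise features for validation.
* **Encoding.** Continuous variables are min-max normalized,
  x′ = (x − min)/(max − min), and cut into 10 equal-width bins (1..10);
  smoking is ordinally coded; binaries pass through.
* **JMIM feature ranking.** Joint mutual information maximization: rank 1 is
  argmax_f I(f; C); each later rank is

      argmax_{f_i ∉ S}  min_{f_s ∈ S}  I(f_i, f_s; C)

  — the "maximum of the minimum" criterion, which rewards features that
  complement the already-selected set S rather than duplicating it.  A
  brute-force oracle and a plain-MI baseline (`mim_rank`) are included.
* **Class-weighted classification.** SVM (RBF) or random forest with the
  minority (positive) class weighted 4:1, 5-fold stratified cross-validation,
  and an incremental curve: the classifier is retrained after adding each
  feature in rank order, yielding accuracy/sensitivity/specificity ± SE per
  subset size k and the k with the best min(sensitivity, specificity)
  trade-off.

The transformers (`CohortEncoder`, `EqualWidthDiscretizer`, `JMIMSelector`)
follow scikit-learn fit/transform conventions and compose with sklearn
pipelines.

## Worked example

```
$ stressecho run-all --variant full --seed 7 --out-dir demo
variant=full best_k=5 accuracy=0.7486 sensitivity=0.6603 specificity=0.7656
```

This generates a study-sized cohort (82 positive / 447 negative) from the
published class-conditional parameters, writes a baseline-characteristics
table (`summary.tsv`), ranks the 16 features (`ranking.tsv`), and evaluates
incremental subsets (`curve.csv`, `curve.png`):

```
$ head -6 demo/ranking.tsv
# seed=7 config=fc3e9a4a8558 version=0.1.0
rank    feature     criterion_bits  min_attained_at
1       ace_arb     0.073051        -
2       prior_cad   0.118471        ace_arb
3       weight      0.084874        prior_cad
4       age         0.080798        prior_cad
```

Rank 1 maximizes individual MI with the outcome (here ACE-I/ARB use, 0.073
bits); at later ranks `criterion_bits` is the max-of-min joint MI and
`min_attained_at` names the already-selected feature at which that minimum
occurred.  Because generated variables are independent given the class, the
ranking reflects marginal effect sizes — strongly separated variables such as
ACE-I/ARB use, prior CAD and sex dominate, while interaction-driven orderings
of the real data cannot be reproduced (see `docs/methods.md`).

```
$ head -3 demo/curve.csv
# seed=7 config=fc3e9a4a8558 version=0.1.0
k,feature_added,accuracy,acc_se,sensitivity,sens_se,specificity,spec_se,...
1,ace_arb,0.642839,0.020974,0.815441,0.056746,0.610936,0.029468,...
```

At k = 1 the weighted SVM catches 81.5% of positive echoes at 61.1%
specificity; the summary line above reports the subset size maximizing
min(sensitivity, specificity).  Same seed, same outputs, byte for byte.

The same analysis is available as a library:

```python
import stressecho as se

spec = se.default_cohort_spec("full")
cohort = se.generate_cohort(spec, 82, 447, seed=7)
ranking, curve = se.run_variant(cohort, "full", seed=7)
print(ranking.features[:4])   # ['ace_arb', 'prior_cad', 'weight', 'age']
print(curve.best_k)           # 5
```

Variants: `no_prior_cad` (drops patients with prior CAD and the prior-CAD
column) and `no_sex` (drops the sex column) mirror the subset analyses.

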