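# mirsig

Ensemble feature selection for reduced miRNA signatures in pan-cancer
classification.

Bulk miRNA expression compendia measure ~1000 stem-loop miRNAs per tumor
sample, but a clinically usable assay needs far fewer. `mirsig` discovers a
reduced *signature* — an ordered subset of k miRNAs — by consensus over a
heterogeneous roster of eight classifier families (three tree ensembles,
five linear models). Each *classifier instance* (one family, one run of
stratified k-fold cross-validation) contributes a ranked top-k feature list;
every feature f is then scored by the fraction of instances that rank it in
their top k:

    s_f = N_t / N_c

where N_t is the number of instances whose top-k list contains f and N_c is
the number of instances (80 for the default 8 families × 10 runs). The k
highest-scoring features form the signature. The package also ships:

* the standard comparison selectors — univariate ANOVA-F selection (UFS),
  recursive feature elimination (RFE, one feature per iteration, n − k
  classifier fits), LASSO / elastic-net selection with internal 3-fold CV,
  subsampled-SVM ensemble selection (EFS-CLA), and random selection;
* an evaluation battery — repeated stratified-CV accuracy for full vs.
  reduced feature sets, per-class accuracy, tumor-vs-normal and
  subtype-vs-rest binary tasks, paired t / Kolmogorov–Smirnov comparisons,
  and a train-on-one-matrix / test-on-another cross-dataset mode;
* cross-platform mapping — mature-sequence → stem-loop reconciliation and
  the per-feature scale fit X_i = (Z_i·σ_i + μ_i)·a_i that places z-scored
  external (e.g. microarray) expression into the reference intensity space;
* a synthetic data generator with planted discriminative features and a
  simulated second platform, so everything is testable end to end without
  any external data.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

```python
from mirsig import SyntheticSpec, generate_labeled_expression, repeated_cv_accuracy
from mirsig.ensemble import EnsembleConfig, EnsembleFeatureSelection

spec = SyntheticSpec(n_samples=300, n_classes=4, class_proportions=(0.4, 0.3, 0.2, 0.1),
                     n_features=50, n_informative=10, effect_size=2.0, seed=7)
X, labels, planted = generate_labeled_expression(spec)
y = labels["tumor_type"].to_numpy()

cfg = EnsembleConfig(n_runs=2, n_folds=5, top_k_tally=10, signature_size=10,
                     seed=0, n_estimators=50)
results = EnsembleFeatureSelection(X, y, cfg).fit()
print(results.summary())

recovered = len(set(results.selected_features) & set(planted))
print(f"\nplanted features recovered: {recovered}/10")

report = repeated_cv_accuracy(X, y, "logistic_regression",
                              feature_subset=results.selected_features,
                              n_folds=5, n_repeats=2, seed=1)
print(report.summary())
```

Output:

```
Ensemble feature selection
============================================================
families:        gradient_boosting, random_forest, logistic_regression, passive_aggressive, sgd_linear, svc_linear, ridge, bagging_trees
runs x folds:    2 x 5
instances (N_c): 16
tally k:         10
signature size:  10
config digest:   25977720068cc895
------------------------------------------------------------
rank  feature                    N_t     s_f
   1  syn-mir-0007                16   1.000
   2  syn-mir-0013                16   1.000
   3  syn-mir-0014                16   1.000
   4  syn-mir-0015                16   1.000
   5  syn-mir-0029                16   1.000
   6  syn-mir-0039                16   1.000
   7  syn-mir-0041                16   1.000
   8  syn-mir-0037                14   0.875
   9  syn-mir-0038                14   0.875
  10  syn-mir-0020                 8   0.500

planted features recovered: 10/10
logistic_regression on subset[10]: accuracy 0.9683 ± 0.0203 (2x5 stratified CV)
```

Seven features appear in the top-10 list of all 16 classifier instances
(s_f = 1.0); the 10-feature signature recovers all 10 planted informative
features, and a logistic classifier restricted to it reaches ~97% accuracy
on held-out folds.

## Command line

The same functionality is exposed as a CLI; all outputs are deterministic
given `--seed`:

```sh
mirsig simulate --out data/ --seed 0
mirsig select --method ensemble --expression data/expression.tsv \
              --labels data/labels.tsv --k 20 --tally-k 20 --seed 0 --out run/
mirsig evaluate --expression data/expression.tsv --labels data/labels.tsv \
                --family logistic_regression --signature run/signature.tsv \
                --out run/report.json
mirsig compare --signature-a run/signature.tsv --signature-b other/signature.tsv \
               --out run/overlap.json
mirsig map-platform fit --zscores geo.tsv --labels geo_labels.tsv \
                        --reference tcga.tsv --reference-labels tcga_labels.tsv \
                        --out map/
```

A YAML file passed as `mirsig --config cfg.yaml <subcommand>` supplies
defaults that flags override.

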