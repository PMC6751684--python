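# Methods

## The problem

A pan-cancer miRNA expression compendium (thousands of tumor samples, ~28
tumor types, ~1000 stem-loop miRNA features measured as reads-per-million)
supports accurate tumor-type classification, but clinical assays cannot
measure a thousand features. The goal is a *reduced signature*: an ordered
subset of k miRNAs (k ≈ 10% of the features) that retains essentially the
full matrix's classification accuracy and is stable across classifier
families and measurement platforms.

## Consensus feature selection

Any single feature-selection method inherits the biases of its underlying
model. The method implemented here instead aggregates *rank information* from
a heterogeneous roster of eight classifier families, grouped in two
typologies:

* **tree ensembles** — bagging, random forest, gradient boosting (300
  predictors each by default): a feature's importance within one fitted
  ensemble is the raw count of internal splits made on it across all trees
  (frequency, not impurity-weighted);
* **linear models** — logistic regression, passive-aggressive, ridge, SGD,
  linear-kernel SVC: a feature's importance is the sum over class rows of the
  absolute value of its coefficient. Multiplying all coefficients by a
  constant leaves the ranking unchanged, so the heterogeneous scales never
  mix: only the within-instance ordering is consumed.

A *classifier instance* is one (family, run) pair. Each run draws a fresh
stratified k-fold partition (default 10 folds), fits the classifier on each
training partition — with standardization (zero mean, unit variance,
population-SD convention) learned on that partition only — and averages the
per-fold importance vectors into one vector, which is truncated to a ranked
top-k list (default k = 100). With 8 families × 10 runs, N_c = 80 instances
contribute. Each feature f is scored by the fraction of instances whose
top-k list contains it:

    s_f = N_t / N_c,

and the signature is the k highest-scoring features (ties: higher N_t, then
alphabetical name — the tally is membership-based, so an ensemble of a single
instance orders its tied features alphabetically). Weighted rank-aggregation
schemes exist but add parameters to tune; the plain appearance fraction is
deliberately parameter-free.

Whether importance should be extracted once per run or once per fold is a
genuinely open protocol choice; this package averages the fold-level vectors
within a run, which uses every fold's fit while keeping one ranked list per
instance (so N_c = families × runs). Instance sub-seeds are derived from the
run seed by fixed enumeration order, so results are independent of execution
order and reproducible byte-for-byte.

Failure handling: an instance whose classifier fails to converge is skipped
with a warning and N_c is decremented; the score denominator always equals
the number of lists actually tallied.

## Baseline selectors

For comparison the package ships the standard selectors, all returning
exactly min(k, n) unique features:

* **UFS** — one-way ANOVA F per feature; constant features score 0.
* **RFE** — recursive elimination with a linear SVC, removing exactly one
  lowest-|coefficient| feature per iteration: n − k fits (1046 → 100 costs
  946 fits).
* **LASSO / elastic net** — one-vs-rest penalized regressions with the
  regularization strength chosen by an internal 3-fold CV; features ranked by
  summed |coefficient|; zero-coefficient features pad the tail (flagged).
* **EFS-CLA** — per iteration, 40 linear SVCs on random 50% subsamples,
  averaged |weights|, bottom E = 20% (floored, ≥ 1) of survivors dropped.
  The terminal step is defined here as: stop before a reduction would
  undershoot k and trim to exactly k by lowest averaged weight, giving the
  survivor schedule 1046 → 837 → … → 114 → 100.
* **random** — uniform selection without replacement, the chance reference.

## Evaluation battery

Accuracy is the plain fraction of correct predictions (micro accuracy);
per-class accuracy is each class's recall, reported separately, and the
global accuracy is exactly the class-size-weighted mean of the per-class
values. `repeated_cv_accuracy` runs repeated stratified CV (fresh folds per
repeat, train-only standardization per fold). Binary tasks (tumor-vs-normal
tissue, one-subtype-vs-rest) are built by a predicate over the label table
and keep stratification downstream. Paired comparisons use a two-sided
paired t-test on fold-aligned accuracies (a zero-variance difference vector
is reported with a degenerate flag, not an error) or a two-sample
Kolmogorov–Smirnov test for unaligned samples. A cross-dataset mode trains
on one matrix and tests on another, automatically intersecting features and
reporting the overlap count.

## Cross-platform mapping

Microarray platforms measure mature sequences while the reference
(sequencing) compendium counts stem-loops, so external matrices are first
reconciled by copying each stem-loop's most common mature-sequence column
(hsa-miR-10b → hsa-mir-10b; stem-loops sharing one mature sequence, like
hsa-mir-135a-1/-2, receive identical copies). Z-scored external expression
is mapped into reference intensities per feature i by

    X_i = (Z_i · σ_i + μ_i) · a_i,

with μ_i, σ_i the reference mean/SD and a_i > 0 a platform-dependent scale,
fitted by minimizing the RMSE between integer class codes predicted by a
classifier trained on the standardized reference data and the actual codes
(class codes are fixed by sorted class-name order on the reference data;
the error is standard RMSE — square, mean, root).

**Numerical design.** This objective is piecewise constant in `a` with a
large degenerate minimizer set: global search finds zero-RMSE scales far
from the generating truth, and single coordinates are nearly unidentifiable.
The fit is therefore anchored. Two start points are evaluated — the user
init (default all-ones) and a label-free *moment anchor*
a_i = μ_i / mean(Z_i·σ_i + μ_i), which aligns the average external intensity
with the reference mean — and the better one is refined by a seeded (1+1)
evolution strategy with log-normal mutations (σ = 0.05 in log space).
Acceptance adds a proximity penalty 0.1 · mean|log(a/start)| so that among
comparable-RMSE scales the one nearest the start wins, the usual
regularization of an ill-posed inverse; the penalty weight makes a 10%
all-coordinate drift cost about one misclassified sample on a few-hundred
sample external set. The returned scale is guaranteed not to have a worse
pure RMSE than the init, the evaluation count is recorded, and the whole
search is deterministic given its seed. On a noiseless simulated platform
with per-feature scales in [0.5, 2] (20 features, 4 classes) the fit
recovers the scale with ~7–15% median relative error; identifiability
through the classifier alone is loose, and that tolerance should be kept in
mind on real data.

## Synthetic data generator

The generator emulates the compendium's structure, not its biology:

    log X[s, f] = b_f + shift[class(s), f] + ε,  ε ~ N(0, noise_sd)

with per-feature baselines b_f ~ N(base_loc = 2, base_scale = 1) and
class-specific shifts N(0, effect_size) on a planted subset of informative
features only. Values are exponentiated, so expression is positive and
heavy-tailed like RPM data. Class sizes follow largest-remainder
apportionment of the requested proportions (within one sample of exact).
Optional tumor/normal status replaces the tumor-class shift with one shared
normal-tissue shift; optional molecular subtypes are assigned within the
largest class. A compendium-scale label table reproduces the exact 28-class
tumor/normal counts (8023 TT / 634 NT) for label-level experiments. A second
platform is simulated by inverting the z-score mapping with known per-feature
scales plus optional noise.

Default benchmark: 600 samples, 8 classes with proportions
0.3/0.2/0.15/0.1/0.1/0.05/0.05/0.05, 200 features, 20 informative, effect
size 1.5 (log-space units against noise SD 1) — small enough for
minutes-scale runs.

What the generator does *not* emulate: miRNA co-expression covariance,
batch effects beyond the per-feature linear platform model, count-level
sampling noise, and platform-specific probe chemistry. Passing tests
therefore demonstrate the correctness and internal consistency of the
procedures, not clinical performance on real cohorts.

## Benchmark problem sizes

The packaged benchmark experiments run the full 8-family roster with one run
of 5-fold CV per family and 50 trees per tree ensemble, tallying and
selecting k = 20 of 200 features (the same 10% compression as 100 of 1046).
Signature parsimony is checked with 10-fold CV (one repeat, 50 trees) per
family on both feature sets. On this benchmark the ensemble signature
recovers all 20 planted features and no family loses more than one
percentage point of accuracy relative to the full matrix — the five linear
families *gain* 15–33 points, because 180 pure-noise features actively hurt
them, so the parsimony check is one-sided (the signature may not lose more
than 3 points).

## Known limitations

* Tree split counts are not depth- or sample-weighted; rare deep splits
  count as much as the root split.
* The linear-SVC family is backed by liblinear (one-vs-rest squared-hinge),
  the fast linear-kernel implementation, not the quadratic-programming SVC.
* The platform scale is identified only up to the classifier's decision
  regions; with few external samples or weak class separation the fitted
  scale inherits the moment anchor's sampling error.
* Multiclass penalized selection uses one-vs-rest aggregation; a true
  multinomial group-lasso would couple the classes.
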