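# Methods

This note documents the statistical model, the numerical choices and the
limits of what the test suite demonstrates. Notation: X ∈ R^{d×N} stacks
all features (the in-memory container stores samples as rows and
transposes through accessors), Y ∈ R^{c×N} is the one-hot class
indicator, W ∈ R^{d×c} the coefficient matrix, and the d rows of W are
partitioned into modality blocks mirroring the dataset.

## Synthetic cohorts

The generator emulates a two-block imaging-genetics case/control cohort.

* **Imaging block** — unit-variance normal features. A planted
  informative feature shifts its class-k mean by `k · effect_size` SD;
  all other features are iid N(0, 1) across classes. This is the
  simplest structure under which the Fisher score has a known population
  value, which the sanity tests exploit.
* **Genotype block** — each SNP is a sum of two Bernoulli minor-allele
  draws (values 0/1/2). Non-informative SNPs share one minor-allele
  frequency (default 0.3, a common-variant frequency typical of
  genotyping arrays; real allele-frequency spectra are not modelled).
  Informative SNPs use class-specific frequencies separated by
  `snp_effect` (default 0.25).
* Defaults mirror the target application: 25 subjects per class, 95
  imaging features, 916 SNPs, 5 planted informative features per block.
* Ground-truth indices are returned beside the dataset, never inside it,
  so they cannot leak into the pipeline.

Not emulated: linkage disequilibrium, population stratification, missing
genotypes, covariate confounding, and correlated morphometric measures.
Passing recovery tests on these cohorts therefore shows the selector
detects independent mean/frequency shifts at realistic sample sizes — not
that it untangles correlated real-world signal.

## Normalization

Min–max for imaging (training outputs in [0, 1)), z-score with the N−1
sample SD for genotypes; in both schemes a guard ε = 10⁻⁸ (inside the
square root for z-score, added to the range for min–max) maps constant
columns to 0 instead of dividing by zero. Parameters are estimated on
training folds only and frozen; transformed test values may fall outside
the training range and are deliberately not clipped. Optional covariate
residualization (ordinary least squares per feature on covariates plus
intercept, with a QR-with-pivoting rank check that names collinear
columns) is meant for real cohorts; synthetic pipelines skip it.

## Fisher filtering

The score uses the sample-size-weighted within-class divergence
Σ_k n_k Σ_{j∈k} (x_ij − μ_i^k)² in the denominator — note the n_k
weighting, which differs from the unweighted pooled sum and is used here
deliberately. ε = 10⁻⁸ is added to the denominator rather than dropping
zero-variance features, so degenerate SNP columns keep a defined (and,
when their class means differ, very large) score. Ranking is descending
with ties broken by ascending index; the default retained count m equals
the imaging-block width, bringing the two blocks to comparable size.
Filtering is refit inside each CV training fold. The score is computed
one column at a time by construction, so it cannot credit features that
are only jointly informative.

## Joint selection objective and solver

The loss is squared Frobenius error ½‖WᵀX − Y‖²_F — the standard choice
in the group-sparse multi-task literature, and the one that admits a
closed-form reweighted solve. Two penalties act together: γ₂‖W‖_{2,1}
couples the c tasks and removes whole features; γ₁‖W‖_{G1} (sum of
per-(class, block) sub-vector norms) moves sparsity *between* modalities
so a weak-but-informative genotype block survives alongside imaging.

**Intercept.** The loss is fitted with an unpenalized per-class offset,
implemented by centering X and Y across samples before the solve
(`fit_intercept=True`, default). Without it the weights must reproduce
the class base rates from non-centered min–max features, which measurably
corrupts the importance ranking; with it W responds only to between-class
structure.

**Solver.** Iteratively reweighted least squares: with every norm
smoothed as √(·² + ε_s), ε_s = 10⁻⁸, the penalties admit quadratic
majorizers whose minimizer per class j solves
(XXᵀ + diag(γ₂/r + γ₁/b_j)) w_j = X y_jᵀ, where r_i = √(‖w_{i:}‖² + ε_s)
and b_j holds the per-block column norms. Each sweep decreases the
smoothed objective monotonically; the recorded trace is that smoothed
objective (the exact-norm objective is available separately and differs
by at most O(√ε_s) per term). Initialization is the ridge solution with
ridge constant γ₁ + γ₂; nothing in the iteration is random, so fits are
bit-reproducible. Convergence: relative objective change < 10⁻⁶ or 200
iterations. At γ₁ = γ₂ = 0 the solver short-circuits to the (minimum-norm)
least-squares solution.

**Hyperparameter scale.** The loss sums over samples, so it is of order
N while each penalty is of order 1; γ values therefore trade off against
cohort size. The defaults γ₁ = γ₂ = 10 correspond to roughly 0.1 per
sample at the N ≈ 100 cohorts this method targets, and were chosen by a
one-time calibration on synthetic cohorts with planted ground truth
(weaker settings leave the d ≈ N least-squares component underdetermined
and the importance ranking noisy). An inner grid search is deliberately
absent so headline runs stay deterministic.

## Selection, weighting, classification

Importance of feature i is Σ_j |w_ij|; the top k = 5 per modality are
kept (ties to the lower index), importances are normalized to sum to one
within each modality (a max-abs variant is available via
`weight_norm="max"`), and selected columns of the *normalized* feature
matrix are multiplied element-wise by their weights. An all-zero
importance block raises an error rather than returning an arbitrary set.

The classifier is a linear SVM. Because sum-to-one weights shrink the k
selected columns by about 1/k, a margin penalty tuned for unit-scale
inputs would over-regularize; the default C = 10 compensates (performance
is flat for C ≥ 10, so the exact value is uncritical). Sensitivity and
specificity treat the later disease stage as positive; they are reported
as NaN for cohorts with more than two classes.

## Cross-validation protocol

Stratified k-fold (default five); per-class fold counts differ by at most
one, and `n_folds = N` yields leave-one-out. Every stage — normalization,
Fisher filter, selector, SVM — is refit per training fold and frozen
before the test split is touched; the fold result carries fingerprints of
all fitted state so leakage can be audited by re-running with altered
test labels. Selection frequency (how many folds chose each feature) is
the stability report used to nominate biomarkers.

## Problem sizes used in the checks

Recovery and accuracy properties are exercised on cohorts of 50 subjects
per class with 50 imaging features and 200 SNPs (5 planted informative
per block, imaging effect 1.0 SD, MAF shift 0.25), 20 cohorts per
property; the structural full-scale run uses 50 per class with 95 + 916
features, top-m 95 and k = 5. These sizes keep every property at the
regime the method targets (d ≈ N after filtering) while remaining cheap
to simulate.

## Known limitations

* Measured on the synthetic conditions above, mean planted-feature recall
  is ≈ 0.98 for imaging and ≈ 0.73 for SNPs (the SNP ceiling is
  information-theoretic: a direct Fisher top-5 oracle on the same cohorts
  reaches only ≈ 0.78 at a 0.25 MAF shift with 50 subjects per class).
* On cohorts linearly separable in the imaging block, cross-validated
  accuracy plateaus near 99.3% rather than exactly 100%: the pipeline by
  design forwards five weak genotype columns, renormalized to full
  within-modality weight, to a max-margin classifier that is not
  Bayes-optimal. Restricting the classifier to the selected imaging
  features alone is perfect on every measured fold.
* Fisher filtering is univariate; SNPs informative only in combination
  are filtered out before the joint stage can see them.
* Multi-class (c > 2) fitting is supported by the indicator formulation,
  but the evaluation metrics and the positive-class convention are
  designed for the binary staging contrasts.
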