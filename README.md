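# mmtfs — multi-modal multi-task feature selection for imaging genetics

`mmtfs` selects small, interpretable panels of biomarkers from two
heterogeneous per-subject feature blocks — continuous structural-MRI
morphometry (cortical thickness and regional volumes) and SNP genotypes in
additive 0/1/2 coding — for classifying stages of neurodegenerative
disease (healthy control, early/late mild cognitive impairment, Alzheimer's
disease). Genotype panels are orders of magnitude wider than imaging
panels and individually much weaker, so naive joint selection either drowns
in SNPs or discards them entirely; `mmtfs` addresses both failure modes.

## Method

Given a cohort of N subjects with d features partitioned into modality
blocks and class labels coded as a one-hot indicator Y ∈ R^{c×N}:

1. **Normalization.** Imaging features are min–max scaled,
   x̃ = (x − x_min)/(x_max − x_min + ε); genotypes are z-scored,
   x̃ = (x − x̄)/√(s² + ε), with parameters fit on training data only.
2. **Fisher-score filtering** of the genotype block. Feature i scores
   F(x_i) = Σ_k n_k (μ_i^k − μ_i)² / (Σ_k n_k Σ_{j∈k} (x_ij − μ_i^k)² + ε),
   and the top *m* SNPs (default: the imaging-block width) survive,
   bringing the two blocks to comparable widths.
3. **Joint multi-task selection.** Solve

       min_W  ½‖WᵀX − Y‖²_F + γ₁‖W‖_{G1} + γ₂‖W‖_{2,1}

   where ‖W‖_{2,1} = Σ_i ‖w_{i:}‖₂ zeroes whole features across tasks and
   the group-l1 norm ‖W‖_{G1} = Σ_classes Σ_blocks ‖w_(block, class)‖₂
   keeps sparsity *between* modalities so the weak modality is not
   discarded wholesale. The solver is a deterministic iteratively
   reweighted least squares (IRLS) scheme with smoothed norms and a
   monotonically decreasing objective.
4. **Selection and reweighting.** Feature importance is Σ_j |w_ij|; the
   top k = 5 features per modality are kept, their importances normalized
   to sum to one within each modality, and each surviving column is
   multiplied element-wise by its weight.
5. **Evaluation.** Stratified fivefold cross-validation with a linear SVM,
   the whole pipeline refit inside every training fold (leakage-free),
   reporting accuracy/sensitivity/specificity and per-feature selection
   frequency across folds.

Because real imaging-genetics cohorts are access-restricted, the package
ships a synthetic cohort generator (`mmtfs.simulate`) that plants known
class-informative features in both blocks, giving every stage a
ground-truth test surface.

## Worked example

```sh
python examples/04_cross_validation.py
```

generates a 100-subject cohort (50 per class, 50 imaging features + 200
SNPs, 5 planted informative features per block, 1.5 SD imaging effect,
0.25 MAF shift) and prints:

```
fold 0: accuracy  95.0%  sensitivity  90.0%  specificity 100.0%
fold 1: accuracy  95.0%  sensitivity 100.0%  specificity  90.0%
fold 2: accuracy  85.0%  sensitivity  80.0%  specificity  90.0%
fold 3: accuracy  90.0%  sensitivity  80.0%  specificity 100.0%
fold 4: accuracy  90.0%  sensitivity  90.0%  specificity  90.0%
mean:   accuracy  91.0%  sensitivity  88.0%  specificity  94.0%
features selected in all 5 folds: ['img_0001', 'img_0023', 'img_0030', 'img_0037', 'img_0039', 'rs000053', 'rs000081', 'rs000113']
  of which planted: ['img_0001', 'img_0023', 'img_0030', 'img_0037', 'img_0039', 'rs000081', 'rs000113']
```

Per-fold metrics come from the held-out confusion matrix (the later
disease stage is the positive class); features selected in all five folds
are the stable biomarker candidates, and here 7 of the 8 ever-present
features are planted ground truth. The other examples
(`examples/01…03_*.py`) walk through cohort simulation, Fisher filtering
and the joint selector individually.

The same pipeline is scriptable from the shell:

```sh
mmtfs simulate --n-per-class 50 --d-imaging 95 --d-snp 916 --seed 1 --out scratch/cohort
mmtfs run --out scratch/run --seed 1           # simulate → normalize → fisher → select → evaluate
```

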