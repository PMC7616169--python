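# cardicca

Multimodal deep canonical correlation analysis for two-view cardiac latent
cine sequences, with fused **and single-view** treatment-response
classification.

## The problem

Cardiac resynchronisation therapy (CRT) helps many heart-failure patients —
but roughly a third gain little or no benefit, and selecting likely
responders up front is an open clinical problem.  Two imaging views of the
same heart are often available at *training* time: a CMR long-axis
four-chamber cine (the gold standard, but expensive) and an
echocardiographic apical four-chamber cine (cheap and everywhere).  At
*deployment* only echocardiography can be assumed.

`cardicca` is for researchers who have reduced each view's cine loop to a
per-frame latent vector (e.g. the pooled bottleneck of a segmentation
network) and want a classifier that is trained on both views but can
predict from either one alone.  The binary target follows the standard
volumetric rule: *responder* = ≥15% reduction in LV end-systolic volume at
follow-up.

## The model

Each subject contributes one `d × T` latent matrix per view (rows = latent
variables, columns = `T = 25` canonical frames after piecewise-linear cycle
warping anchored at ED and ES).  A deep CCA with convolutional branches
aligns the two views:

```
(θ₁*, θ₂*) = argmax  corr(f₁(X₁; θ₁), f₂(X₂; θ₂))
```

where each `f_v` is a small CNN (conv pairs at 8, 16, 32 channels, 3×3
kernels, max pools between pairs, 1×1 projection + global average pooling
to a `k`-vector) and `corr` is the sum of the top canonical correlations of
the branch outputs — the nuclear norm of the whitened cross-covariance
`Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2}`.  A closed-form linear CCA fitted on the
trained branch outputs yields aligned projections `V₁, V₂`; the fusion
layer blends them as `F = α·V₁ + β·V₂` (α = β = 0.5) and an RBF-SVM
classifies `F`.  Because `V₁ ≈ V₂` by construction, the same SVM accepts a
single view's projection at test time.

Everything is numpy: the branches, their backprop and the analytic
correlation-objective gradient are implemented and verified in-package
(finite differences; `scipy.signal` as the convolution oracle).  Training
is a deterministic function of data, hyperparameters and a seed.

A seeded synthetic cohort generator with closed-form population canonical
correlations stands in for clinical data: a smooth periodic shared
trajectory per subject, class mean-shift on discriminative components,
view-specific orthonormal mixing, noise and native frame counts.

## Worked example

```python
from cardicca import CohortConfig, generate_cohort
from cardicca.evaluation import nested_cross_validate, reduced_grids

cfg = CohortConfig(n_subjects=60, prevalence=0.64, effect_size=1.0,
                   d_view1=8, d_view2=8,
                   noise_sd_view1=1.5, noise_sd_view2=1.5, seed=7)
cohort = generate_cohort(cfg)

dcca_grid, svm_grid = reduced_grids()
report = nested_cross_validate(cohort, dcca_grid, svm_grid,
                               outer_folds=5, inner_folds=3,
                               seed=1, epochs=30)
print(report.metrics_table())
```

prints

```
mode           BACC(%)    SEN(%)    SPE(%)
fused            96.53     97.22     95.83
view1_only       96.53     97.22     95.83
view2_only       84.72     94.44     75.00
```

Reading: on a 60-subject cohort with a one-standard-deviation class shift
buried under view noise, the nested cross-validation (outer folds score,
inner folds pick `k`, learning rate, `γ`, `C`) pools out-of-fold
predictions into a balanced accuracy of 96.5% when both views are present.
Feeding **only** view 1's projection to the very same SVM loses nothing
here; view 2 alone drops to 84.7% — the cross-modal transfer the
architecture is designed for, with the remaining gap reflecting the noise
in that view.  `report.folds[f].selected` records the winning hyperparameters per
fold; `report.predictions(mode)` returns pooled out-of-fold predictions.

The same pipeline is scriptable from the shell:

```bash
cardicca --seed 7 simulate  --container cohort.h5 --manifest cohort.csv --n-subjects 60
cardicca --seed 7 crossval  --container cohort.h5 --report cv.json --reduced-grid
cardicca --seed 7 resample  --container cohort.h5          # canonical matrices
cardicca --seed 7 train-dcca --container cohort.h5 --checkpoint dcca.h5
cardicca --seed 7 train-classifier --container cohort.h5 --checkpoint dcca.h5 --classifier svm.pkl
cardicca --seed 7 predict   --container cohort.h5 --checkpoint dcca.h5 \
         --classifier svm.pkl --mode view2_only --out predictions.csv
```

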