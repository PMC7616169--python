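# Methods

## Problem setting

Roughly a third of heart-failure patients who receive cardiac
resynchronisation therapy (CRT) do not benefit from it.  The prediction
target here is the standard volumetric response label: a patient is a
*responder* if left-ventricular end-systolic volume falls by at least 15% at
follow-up.  The inputs are not images but *latent cine sequences*: for each
subject and each of two imaging views (a CMR long-axis four-chamber cine and
an echocardiographic apical four-chamber cine), a segmentation network's
bottleneck activations are summarized to one d-vector per frame.  The
package consumes these per-frame latent vectors together with cardiac-cycle
timing annotations (ED and ES frame indices) and a binary response label.

The central idea is multimodal training with unimodal deployment: both views
are available when the model is trained, but at test time the model should
work from either view alone — in practice from echocardiography, the cheap
and ubiquitous modality.

## Pipeline

### Temporal normalisation

Native cine lengths vary by vendor and heart rate, so each latent sequence
is warped to a canonical grid of `T = 25` frames by a two-segment
piecewise-linear time map anchored at ED (cycle start, native frame 0) and
ES.  ED maps to canonical column 0, ES to column
`round(canonical_es_fraction * (T - 1))`, and the last native frame to
column `T - 1`; each canonical column linearly interpolates its two
bracketing native frames, per latent dimension.  Consequences that the test
suite asserts exactly: endpoint frames are conserved, the ES frame is hit
exactly (no canonical column straddles the anchor), the warp is strictly
increasing, and resampling an already-canonical sequence is the identity.

`canonical_es_fraction` defaults to 0.35 — a physiologically typical systole
fraction — and is configurable; with `T = 25` this places ES at column 8.
Only ED and ES are used as anchors: the minimal scheme consistent with
timing-based warping.  No smoothing is applied.  ES is required to lie
strictly between ED and the last frame so both warp segments are
non-degenerate.

The result is one `d x T` latent matrix per subject and view (rows = latent
variables, columns = canonical frames).

### Deep CCA alignment

Each view's latent matrix passes through its own small CNN branch: three
conv pairs at 8, 16 and 32 channels (3x3 kernels, stride 1, ReLU after every
conv), a 2x2 max pool between consecutive pairs, then a 1x1 convolution to
`k_dcca` channels and global average pooling to a `k_dcca`-vector.  The two
branch parameter sets θ1, θ2 are trained jointly to maximize

    corr(f1(X1; θ1), f2(X2; θ2)),

realized as the sum of the top canonical correlations of the two branch
output blocks: with centered outputs H1, H2, covariance blocks
Σ11, Σ22 (each ridged by `cov_reg`) and Σ12, the objective is the nuclear
norm of `T = Σ11^{-1/2} Σ12 Σ22^{-1/2}`, a value in `[0, k_dcca]`.  Its
analytic gradient (via the SVD of `T`) is hand-derived and verified against
central finite differences to 1e-4 relative error; all layers implement
their own backprop in numpy, and the convolution forward pass is checked
against `scipy.signal.correlate2d`.

After branch training, a closed-form linear CCA is fitted on the
final-epoch branch outputs of the full training set.  Its projections V1,
V2 are the model's aligned representations; projecting a new subject needs
only one view's branch and its side of the projection.

Numerical and design choices, each exposed as a parameter:

* **Optimizer** — Adam with first-moment decay 0.9, second-moment decay
  0.999, epsilon 1e-8; 500 epochs and batch size 10 by default.
* **Full-batch loss** — the whitened cross-covariance of a 10-sample batch
  is rank deficient for `k_dcca >= 10`, so by default every optimization
  step evaluates the objective on the full training set (cohorts are tens to
  hundreds of subjects).  A literal per-mini-batch loss mode exists behind
  `minibatch_loss=True` with `k_corr` capped at `batch_size - 1`.
* **Head** — global pooling alone cannot map 32 channels onto an arbitrary
  `k_dcca`; a 1x1 convolution does the channel projection first.
* **Padding** — odd spatial dims are zero-padded to even before each pool
  (`d x 25` inputs are odd-width); past the first ReLU activations are
  nonnegative, so zero padding is neutral for the max.
* **Initialization** — seeded uniform fan-in; the whole training loop is a
  deterministic function of (data, hyperparameters, seed).
* **Covariance ridge** — `cov_reg = 1e-4` on both auto-covariance blocks,
  standard deep-CCA practice; covariances normalized by `n - 1`.
* **Retained correlations** — the objective sums all `k_dcca` canonical
  correlations by default; `k_corr` allows truncation.  Ties among singular
  values are broken by index order; the gradient is asserted only away from
  ties.
* **Sign convention** — each view-1 canonical direction is scaled so its
  largest-magnitude loading is positive, and the paired view-2 direction is
  flipped with it so the canonical covariance stays nonnegative.  Flipping
  the views independently could silently negate the pairing.
* **Final-epoch weights** are used; no early stopping or epoch selection.

A degenerate *linear probe* configuration (single 1x1 convolution, no
activation, no pooling, latent dimensions laid out as input channels) makes
the branch an exact affine map of the per-dimension temporal means.  In
this regime the achievable objective equals the closed-form linear-CCA total
correlation of the column-averaged inputs, which the tests verify to within
0.02 — the main equivalence oracle for the training loop.

### Fusion and classification

The aligned projections are blended as `F = α·V1 + β·V2` with `α = β = 0.5`
(an even blend; the weights are configuration, not learned), and an RBF-SVM
classifies F into responder / non-responder.  `class_weight='balanced'` is
the default because response cohorts are imbalanced (prevalence near 0.64)
and balanced accuracy is the selection metric.  Hard decisions only; no
probability calibration.

Single-view inference feeds `V_view` in place of F.  Because the RBF kernel
is not scale-invariant there are two defensible conventions, both
implemented: `single_view_scale='raw'` passes `V_view` unchanged (the
default — with `α = β = 0.5` and CCA-aligned views, `F ≈ V_view` whenever
the views agree), and `'fusion-weighted'` passes `α·V_view`.

### Evaluation

Balanced accuracy `BACC = (SEN + SPE) / 2`, sensitivity `TP/(TP+FN)`
(responder recall) and specificity `TN/(TN+FP)` are computed from pooled
out-of-fold confusion counts.  Performance estimation is a stratified
nested cross-validation (5 outer x 5 inner folds by default): the inner
grid search over `(k_dcca, lr) x (gamma, C)` selects by mean inner
fused-mode BACC — ties broken toward smaller `k_dcca`, then larger learning
rate, then smaller cost, then smaller gamma, preferring simpler models
deterministically — and the winner is retrained on the outer-training fold.
Out-of-fold predictions are stored for all three modes.  The full grids are
`k_dcca ∈ {5,...,35}`, `lr ∈ {0.01, 0.001, 0.0001}`, `γ ∈ {0.1,...,1e-4}`,
`C ∈ {1,...,1000}`; `--reduced-grid` shrinks them (k=5; lr ∈ {0.01, 0.001};
γ ∈ {0.1, 0.01}; C ∈ {1, 10}) for desk-scale runs.

Methods are compared by a two-sided paired Student t-test on per-outer-fold
BACC values (99% confidence by default).  The per-fold BACC is the chosen
replicate unit; per-subject correctness indicators would be an alternative
reading and are not implemented.  A zero-variance nonzero difference is
reported as exact-direction significance (p below 1e-12) instead of a
division by zero; identical scores give p = 1.  Report tables round half-up
to two decimals on the percent scale, so the printed-table identity
`BACC = (SEN + SPE)/2` is reproducible from printed SEN/SPE.

## Synthetic cohort generator

No public paired two-view latent cohort exists, so the generator is
first-class, tested code that emulates the relevant structure.  Per
subject, a shared trajectory

    z_i(t) = μ_i + Σ_h a_ih cos(2πht) + b_ih sin(2πht),
    a_ih, b_ih ~ N(0, 1/n_harmonics)

is periodic and smooth (defaults: 3 harmonics) with unit variance at every
cycle phase.  Responders (Bernoulli with prevalence 0.64, matching a 32/50
clinical cohort) receive a constant mean shift of `effect_size` on each of
the first `q_discriminative` components; since components are
unit-variance, `effect_size` is the per-component standardized class
separation, and it is a level shift, not a shape change — the simplest
controllable effect for power and recovery studies.  Each view observes

    x_v(t) = A_v z(t) + ε_v(t),   ε_v ~ N(0, noise_sd_v² I)

at its own native frame phases (counts drawn uniformly per subject from
view-specific ranges, defaults 20–40 and 30–60, so the resampling stage is
always exercised; ES placed at a uniform 30–45% of the cycle).  The mixing
maps A_v have orthonormal columns, drawn once per cohort from a seeded
Gaussian QR: the view geometry is fixed, as two instruments viewing the
same organ.

Because the model is Gaussian-linear, the population canonical correlations
between the stationary observation laws follow in closed form: with
`C_z = I + p(1-p) m mᵀ` (the label-mixture covariance, `m` the shift
vector), the blocks are `S_vv = A_v C_z A_vᵀ + sd_v² I` and
`S_12 = A_1 C_z A_2ᵀ`, and the correlations are the singular values of the
whitened cross-covariance (support-restricted pseudo-inverse square roots,
so noiseless rank-deficient covariances are handled).  Sampling convention
for recovery checks: one paired observation per subject at the ED frame — a
common cycle phase across views — giving i.i.d. draws for which the
textbook standard error `(1-ρ²)/√n` applies; pooling all frames would bias
no estimate but would break that error formula.

What the generator does *not* emulate: real segmentation-network latent
spaces have unknown, surely non-Gaussian and nonstationary statistics; the
class effect in real cohorts is unlikely to be a pure mean shift; noise is
neither white nor homoscedastic across frames.  Passing recovery tests on
this generator demonstrates that the estimation machinery is correct under
its stated model, not that the clinical effect is detectable at any given
cohort size.

## Null calibration

Permutation-null replicates freeze the deep CCA transform and permute only
the labels before the SVM-level nested cross-validation.  This is exact,
not an approximation: the alignment stage is unsupervised, so a label
permutation cannot change it, and re-training it per replicate would
reproduce the identical features at fifty times the cost.  Pooled null
BACC concentrates near 50% with spread set by the cohort size
(about ±4 percentage points standard deviation at n = 200).

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run the heavier experiments at
sizes the package treats as its standard desk-scale configurations:
8-dimensional views with 4 shared components (2 discriminative), cohorts of
200 subjects for classification recovery (effect size 3) and 2000 subjects
for canonical-correlation recovery, 30 training epochs with the reduced
grids for nested cross-validation, and 50 permutation replicates.  The
100-instance CCA oracle sweep uses d ≤ 4, n ≤ 100, where the brute-force
direction search is reliable to 1e-6.

## Known limitations

* The real-image path is an adapter contract only: how a segmentation
  network's spatial bottleneck becomes a per-frame vector (the package
  assumes spatial averaging) is a choice, and no segmentation backend is
  bundled.
* Exactly two views; no kernelized, sparse or multi-view (>2) CCA variants.
* Fusion weights are fixed, not learned; no alternative kernels for the
  classifier; no probability outputs.
* With cohorts of tens of subjects, nested-CV estimates have wide
  confidence intervals; the paired t-test on five fold-level replicates has
  limited power and its normality assumption is informal.
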