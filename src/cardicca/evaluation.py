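"""Metrics, nested cross-validation and paired significance comparison.

Balanced accuracy (BACC) — the mean of sensitivity (responder recall) and
specificity (non-responder recall) — is the headline metric throughout,
because response cohorts are imbalanced.  Performance is estimated by a
stratified nested cross-validation: outer folds provide unbiased test sets
while an inner stratified grid search over the DCCA hyperparameters
(k_dcca, learning rate) crossed with the SVM grid (gamma, cost) selects the
configuration with the best mean inner fused-mode BACC.  The winning
configuration is retrained on the full outer-training fold, out-of-fold
predictions are stored for all three inference modes (fused, view-1 only,
view-2 only), and pooled confusion counts give the reported metrics.

Methods are compared by a paired two-sided Student t-test on per-outer-fold
BACC differences, at 99% confidence by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .classify import (COST_GRID, GAMMA_GRID, FusionWeights, SVMConfig, fuse,
                       train_response_classifier)
from .dcca import DeepCCA, K_DCCA_GRID, LEARNING_RATE_GRID
from .exceptions import StratificationError, UndefinedMetricError, ValidationError
from .preprocessing import (CANONICAL_ES_FRACTION, CANONICAL_T, CycleResampler)

__all__ = ["ConfusionCounts", "sensitivity", "specificity", "balanced_accuracy",
           "confusion_from_predictions", "round_half_up", "CVReport",
           "nested_cross_validate", "default_grids", "reduced_grids",
           "svm_nested_cv", "permutation_null", "paired_t_test",
           "paired_comparison", "cohort_to_arrays"]

MODES = ("fused", "view1_only", "view2_only")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is 'responder'."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_from_predictions(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """Responder recall: TP / (TP + FN)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives scored")
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """Non-responder recall: TN / (TN + FP)."""
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives scored")
    return counts.tn / (counts.tn + counts.fp)


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean of the two per-class accuracies: (SEN + SPE) / 2."""
    return 0.5 * (sensitivity(counts) + specificity(counts))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding, the convention used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def default_grids():
    """Full hyperparameter grids: (k_dcca, lr) x (gamma, cost)."""
    dcca_grid = [{"k_dcca": k, "learning_rate": lr}
                 for k in K_DCCA_GRID for lr in LEARNING_RATE_GRID]
    svm_grid = [{"gamma": g, "cost": c} for g in GAMMA_GRID for c in COST_GRID]
    return dcca_grid, svm_grid


def reduced_grids():
    """Shrunk grids for desk-scale runs (the `--reduced-grid` mode)."""
    dcca_grid = [{"k_dcca": 5, "learning_rate": 0.01},
                 {"k_dcca": 5, "learning_rate": 0.001}]
    svm_grid = [{"gamma": g, "cost": c} for g in (0.1, 0.01) for c in (1.0, 10.0)]
    return dcca_grid, svm_grid


@dataclass
class FoldResult:
    fold: int
    selected: dict
    test_index: list
    predictions: dict  # mode -> list[int]
    labels: list


@dataclass
class CVReport:
    """Nested-CV outcome: per-fold selections and pooled per-mode metrics."""

    folds: list
    pooled_counts: dict  # mode -> ConfusionCounts
    metrics: dict        # mode -> {"bacc": .., "sen": .., "spe": ..} (fractions)
    subject_ids: list
    fold_assignment: list
    seed: int

    def predictions(self, mode: str = "fused") -> np.ndarray:
        """Pooled out-of-fold predictions in subject order."""
        out = np.full(len(self.subject_ids), -1, dtype=int)
        for fr in self.folds:
            out[np.asarray(fr.test_index, dtype=int)] = fr.predictions[mode]
        return out

    def labels(self) -> np.ndarray:
        out = np.full(len(self.subject_ids), -1, dtype=int)
        for fr in self.folds:
            out[np.asarray(fr.test_index, dtype=int)] = fr.labels
        return out

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "subject_ids": list(self.subject_ids),
            "fold_assignment": [int(f) for f in self.fold_assignment],
            "folds": [
                {"fold": fr.fold, "selected": fr.selected,
                 "test_index": [int(i) for i in fr.test_index],
                 "labels": [int(v) for v in fr.labels],
                 "predictions": {m: [int(v) for v in p]
                                 for m, p in fr.predictions.items()}}
                for fr in self.folds
            ],
            "pooled_counts": {m: asdict(c) for m, c in self.pooled_counts.items()},
            "metrics": {m: {k: float(v) for k, v in d.items()}
                        for m, d in self.metrics.items()},
        }

    def metrics_table(self) -> str:
        """Human-readable BACC/SEN/SPE table on the percent scale (half-up, 2 dp)."""
        lines = [f"{'mode':<12}{'BACC(%)':>10}{'SEN(%)':>10}{'SPE(%)':>10}"]
        for mode in MODES:
            m = self.metrics[mode]
            lines.append(f"{mode:<12}"
                         f"{round_half_up(100 * m['bacc']):>10.2f}"
                         f"{round_half_up(100 * m['sen']):>10.2f}"
                         f"{round_half_up(100 * m['spe']):>10.2f}")
        return "\n".join(lines)


def cohort_to_arrays(cohort, T: int = CANONICAL_T,
                     canonical_es_fraction: float = CANONICAL_ES_FRACTION):
    """Resample a cohort to canonical latent matrices; returns (X1, X2, y, ids)."""
    resampler = CycleResampler(T=T, canonical_es_fraction=canonical_es_fraction)
    x1 = resampler.transform([(s.view1_frames, s.timings_view1) for s in cohort])
    x2 = resampler.transform([(s.view2_frames, s.timings_view2) for s in cohort])
    y = np.array([s.label for s in cohort], dtype=int)
    ids = [s.subject_id for s in cohort]
    return x1, x2, y, ids


def _stratified_kfold(y, n_splits, seed):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError("cohort must contain both classes")
    if counts.min() < n_splits:
        raise StratificationError(
            f"minority class has {counts.min()} subjects, fewer than "
            f"{n_splits} folds: a fold would miss a class")
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def _mean_inner_bacc(fold_baccs):
    return float(np.mean(fold_baccs))


def _selection_order_key(combo):
    """Deterministic tie-break: smaller k_dcca, larger lr, smaller cost, smaller gamma."""
    d, s = combo
    return (d["k_dcca"], -d["learning_rate"], s["cost"], s["gamma"])


def nested_cross_validate(cohort, dcca_grid=None, svm_grid=None,
                          outer_folds: int = 5, inner_folds: int = 5,
                          seed: int = 0, epochs: int = 500,
                          batch_size: int = 10, cov_reg: float = 1e-4,
                          T: int = CANONICAL_T,
                          canonical_es_fraction: float = CANONICAL_ES_FRACTION,
                          weights: FusionWeights = FusionWeights(),
                          class_weighting: str = "balanced",
                          single_view_scale: str = "raw") -> CVReport:
    """Stratified nested cross-validation of the full multimodal pipeline.

    Inner grid search trains one DCCA per (inner fold, DCCA config) — the
    expensive part — and evaluates every SVM config on its projections; the
    winner by mean inner fused-mode BACC is retrained on the outer-training
    fold and applied to the held-out fold in all three modes.
    """
    if outer_folds < 2 or inner_folds < 2:
        raise ValidationError("fold counts must be >= 2")
    if len(cohort) < outer_folds:
        raise ValidationError(
            f"cohort of {len(cohort)} cannot fill {outer_folds} outer folds")
    if dcca_grid is None or svm_grid is None:
        dg, sg = default_grids()
        dcca_grid = dcca_grid or dg
        svm_grid = svm_grid or sg

    x1, x2, y, ids = cohort_to_arrays(cohort, T, canonical_es_fraction)
    outer = _stratified_kfold(y, outer_folds, seed % (2 ** 31))
    fold_assignment = np.empty(len(y), dtype=int)
    folds: list[FoldResult] = []

    for fold_id, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(y)), y)):
        fold_assignment[test_idx] = fold_id
        ytr = y[train_idx]
        inner = _stratified_kfold(ytr, inner_folds,
                                  (seed * 1000 + fold_id + 1) % (2 ** 31))
        scores = {}  # (dcca_idx, svm_idx) -> list of inner BACCs
        for in_fold, (itr, ival) in enumerate(
                inner.split(np.zeros(len(ytr)), ytr)):
            g_tr = train_idx[itr]
            g_val = train_idx[ival]
            for di, dconf in enumerate(dcca_grid):
                dcca = DeepCCA(k_dcca=dconf["k_dcca"],
                               learning_rate=dconf["learning_rate"],
                               epochs=epochs, batch_size=batch_size,
                               cov_reg=cov_reg,
                               seed=(seed * 100003 + fold_id * 101 + in_fold) % (2 ** 31))
                dcca.fit((x1[g_tr], x2[g_tr]))
                v1_tr, v2_tr = dcca.transform((x1[g_tr], x2[g_tr]))
                v1_va, v2_va = dcca.transform((x1[g_val], x2[g_val]))
                f_tr = fuse(v1_tr, v2_tr, weights)
                f_va = fuse(v1_va, v2_va, weights)
                for si, sconf in enumerate(svm_grid):
                    clf = train_response_classifier(
                        f_tr, y[g_tr],
                        SVMConfig(gamma=sconf["gamma"], cost=sconf["cost"],
                                  class_weighting=class_weighting))
                    pred = clf.predict(f_va)
                    bacc = balanced_accuracy(
                        confusion_from_predictions(y[g_val], pred))
                    scores.setdefault((di, si), []).append(bacc)

        combos = sorted(
            scores, key=lambda k: (-_mean_inner_bacc(scores[k]),
                                   _selection_order_key((dcca_grid[k[0]],
                                                         svm_grid[k[1]]))))
        best_d, best_s = combos[0]
        dconf, sconf = dcca_grid[best_d], svm_grid[best_s]

        dcca = DeepCCA(k_dcca=dconf["k_dcca"], learning_rate=dconf["learning_rate"],
                       epochs=epochs, batch_size=batch_size, cov_reg=cov_reg,
                       seed=(seed * 100003 + fold_id * 101 + 97) % (2 ** 31))
        dcca.fit((x1[train_idx], x2[train_idx]))
        v1_tr, v2_tr = dcca.transform((x1[train_idx], x2[train_idx]))
        clf = train_response_classifier(
            fuse(v1_tr, v2_tr, weights), ytr,
            SVMConfig(gamma=sconf["gamma"], cost=sconf["cost"],
                      class_weighting=class_weighting))

        v1_te = dcca.transform_view(x1[test_idx], "view1")
        v2_te = dcca.transform_view(x2[test_idx], "view2")
        scale1 = 1.0 if single_view_scale == "raw" else weights.alpha
        scale2 = 1.0 if single_view_scale == "raw" else weights.beta
        predictions = {
            "fused": clf.predict(fuse(v1_te, v2_te, weights)).tolist(),
            "view1_only": clf.predict(scale1 * v1_te).tolist(),
            "view2_only": clf.predict(scale2 * v2_te).tolist(),
        }
        folds.append(FoldResult(
            fold=fold_id,
            selected={"k_dcca": dconf["k_dcca"],
                      "learning_rate": dconf["learning_rate"],
                      "gamma": sconf["gamma"], "cost": sconf["cost"]},
            test_index=test_idx.tolist(),
            predictions=predictions,
            labels=y[test_idx].tolist(),
        ))

    pooled = {}
    metrics = {}
    for mode in MODES:
        counts = ConfusionCounts()
        for fr in folds:
            counts = counts + confusion_from_predictions(
                fr.labels, fr.predictions[mode])
        pooled[mode] = counts
        metrics[mode] = {"bacc": balanced_accuracy(counts),
                         "sen": sensitivity(counts),
                         "spe": specificity(counts)}
    return CVReport(folds=folds, pooled_counts=pooled, metrics=metrics,
                    subject_ids=ids, fold_assignment=fold_assignment.tolist(),
                    seed=seed)


# ---------------------------------------------------------------------------
# permutation null on frozen features
# ---------------------------------------------------------------------------

def svm_nested_cv(features: np.ndarray, labels, svm_grid=None,
                  outer_folds: int = 5, inner_folds: int = 3,
                  seed: int = 0, class_weighting: str = "balanced") -> float:
    """Pooled BACC of an SVM-level nested CV on fixed (already aligned) features."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if svm_grid is None:
        svm_grid = reduced_grids()[1]
    outer = _stratified_kfold(y, outer_folds, seed % (2 ** 31))
    counts = ConfusionCounts()
    for fold_id, (tr, te) in enumerate(outer.split(x, y)):
        inner = _stratified_kfold(y[tr], inner_folds,
                                  (seed * 1000 + fold_id + 1) % (2 ** 31))
        scores = {si: [] for si in range(len(svm_grid))}
        for itr, ival in inner.split(x[tr], y[tr]):
            for si, sconf in enumerate(svm_grid):
                clf = train_response_classifier(
                    x[tr][itr], y[tr][itr],
                    SVMConfig(gamma=sconf["gamma"], cost=sconf["cost"],
                              class_weighting=class_weighting))
                scores[si].append(balanced_accuracy(confusion_from_predictions(
                    y[tr][ival], clf.predict(x[tr][ival]))))
        best = min(scores, key=lambda si: (-float(np.mean(scores[si])),
                                           svm_grid[si]["cost"],
                                           svm_grid[si]["gamma"]))
        sconf = svm_grid[best]
        clf = train_response_classifier(
            x[tr], y[tr], SVMConfig(gamma=sconf["gamma"], cost=sconf["cost"],
                                    class_weighting=class_weighting))
        counts = counts + confusion_from_predictions(y[te], clf.predict(x[te]))
    return balanced_accuracy(counts)


def permutation_null(features: np.ndarray, labels, n_replicates: int = 50,
                     seed: int = 0, svm_grid=None, outer_folds: int = 5,
                     inner_folds: int = 3) -> np.ndarray:
    """Null distribution of pooled BACC under label permutation.

    The deep CCA transform is unsupervised — permuting labels cannot change
    it — so the null replicates freeze the features and re-run only the
    label-dependent SVM-level nested CV per permutation.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        y_perm = rng.permutation(y)
        out[r] = svm_nested_cv(features, y_perm, svm_grid=svm_grid,
                               outer_folds=outer_folds, inner_folds=inner_folds,
                               seed=int(rng.integers(2 ** 31)))
    return out


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def paired_t_test(scores_a, scores_b, confidence: float = 0.99):
    """Two-sided paired Student t-test on per-fold scores.

    Returns ``(statistic, p_value, significant)``.  A zero-variance nonzero
    difference is reported as exact-direction significance (p below 1e-12)
    rather than a division by zero; identical scores give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("score vectors must be 1-D and equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 folds for a paired test")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, False
        stat = np.inf if d.mean() > 0 else -np.inf
        return float(stat), 0.0, True
    res = stats.ttest_rel(a, b)
    significant = bool(res.pvalue < 1.0 - confidence)
    return float(res.statistic), float(res.pvalue), significant


def paired_comparison(predictions_a, predictions_b, labels,
                      confidence: float = 0.99, fold_assignment=None):
    """Compare two methods' predictions by per-outer-fold BACC differences."""
    pa = np.asarray(predictions_a, dtype=int)
    pb = np.asarray(predictions_b, dtype=int)
    y = np.asarray(labels, dtype=int)
    if fold_assignment is None:
        raise ValidationError("fold_assignment is required (per-fold replicates)")
    fa = np.asarray(fold_assignment, dtype=int)
    if not (pa.shape == pb.shape == y.shape == fa.shape):
        raise ValidationError("prediction, label and fold vectors must align")
    fold_ids = np.unique(fa)
    if fold_ids.size < 2:
        raise ValidationError("need at least 2 folds for a paired comparison")
    scores_a, scores_b = [], []
    for f in fold_ids:
        m = fa == f
        scores_a.append(balanced_accuracy(confusion_from_predictions(y[m], pa[m])))
        scores_b.append(balanced_accuracy(confusion_from_predictions(y[m], pb[m])))
    return paired_t_test(scores_a, scores_b, confidence)
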