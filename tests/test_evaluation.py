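"""Metrics, nested cross-validation mechanics and paired comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cardicca import (ConfusionCounts, balanced_accuracy, paired_comparison,
                      paired_t_test, sensitivity, specificity)
from cardicca.evaluation import (confusion_from_predictions,
                                 nested_cross_validate, reduced_grids,
                                 round_half_up, svm_nested_cv)
from cardicca.exceptions import (StratificationError, UndefinedMetricError,
                                 ValidationError)


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(tp=6, fn=1), 6 / 7),
        (ConfusionCounts(tp=5, fn=0), 1.0),
        (ConfusionCounts(tp=25, fn=5), 25 / 30),
    ])
    def test_sensitivity_exact_ratio(self, counts, expected):
        assert sensitivity(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(tn=5, fp=2), 5 / 7),
        (ConfusionCounts(tn=3, fp=0), 1.0),
        (ConfusionCounts(tn=0, fp=10), 0.0),
    ])
    def test_specificity_exact_ratio(self, counts, expected):
        assert specificity(counts) == pytest.approx(expected, abs=1e-12)

    def test_balanced_accuracy_examples(self):
        assert balanced_accuracy(ConfusionCounts(tp=5, fn=0, tn=4, fp=0)) == 1.0
        assert balanced_accuracy(ConfusionCounts(tp=5, fn=5, tn=0, fp=10)) == 0.25

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tn=5, fp=2))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(tp=5, fn=2))
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(ConfusionCounts(tp=3))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_bacc_identity_and_relabel_symmetry(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        assert balanced_accuracy(c) == pytest.approx(
            0.5 * (sensitivity(c) + specificity(c)), abs=1e-15)
        swapped = ConfusionCounts(tp=tn, fp=fn, fn=fp, tn=tp)
        assert sensitivity(swapped) == specificity(c)
        assert specificity(swapped) == sensitivity(c)
        assert balanced_accuracy(swapped) == pytest.approx(
            balanced_accuracy(c), abs=1e-15)

    def test_round_half_up(self):
        assert round_half_up(77.375) == 77.38
        assert round_half_up(71.985) == 71.99
        assert round_half_up(81.195) == 81.20
        assert round_half_up(55.714999) == 55.71


@pytest.fixture(scope="module")
def tiny_report(small_cohort):
    _, cohort = small_cohort
    dcca_grid = [{"k_dcca": 5, "learning_rate": 0.01}]
    svm_grid = reduced_grids()[1]
    return nested_cross_validate(cohort, dcca_grid, svm_grid,
                                 outer_folds=5, inner_folds=2,
                                 seed=3, epochs=6), cohort


class TestNestedCrossValidation:

    def test_partition_property(self, tiny_report):
        report, cohort = tiny_report
        n = len(cohort)
        for mode in ("fused", "view1_only", "view2_only"):
            assert report.pooled_counts[mode].total == n
            preds = report.predictions(mode)
            assert np.all(preds >= 0)  # every subject predicted exactly once
        covered = sorted(i for fr in report.folds for i in fr.test_index)
        assert covered == list(range(n))

    def test_stratification_keeps_fold_prevalence(self, tiny_report):
        report, cohort = tiny_report
        y = np.array([s.label for s in cohort])
        global_prev = y.mean()
        fa = np.array(report.fold_assignment)
        for f in np.unique(fa):
            fold_y = y[fa == f]
            # within one subject of global prevalence
            assert abs(fold_y.sum() - global_prev * fold_y.size) <= 1.0

    def test_selected_hyperparameters_come_from_grid(self, tiny_report):
        report, _ = tiny_report
        for fr in report.folds:
            assert fr.selected["k_dcca"] == 5
            assert fr.selected["gamma"] in (0.1, 0.01)
            assert fr.selected["cost"] in (1.0, 10.0)

    def test_deterministic_fold_assignment(self, small_cohort):
        _, cohort = small_cohort
        grid = [{"k_dcca": 5, "learning_rate": 0.01}]
        svm = [{"gamma": 0.1, "cost": 1.0}]
        a = nested_cross_validate(cohort, grid, svm, outer_folds=5,
                                  inner_folds=2, seed=9, epochs=3)
        b = nested_cross_validate(cohort, grid, svm, outer_folds=5,
                                  inner_folds=2, seed=9, epochs=3)
        assert a.to_dict() == b.to_dict()

    def test_single_class_cohort_raises(self, small_cohort):
        _, cohort = small_cohort
        responders = [s for s in cohort if s.label == 1]
        with pytest.raises(StratificationError):
            nested_cross_validate(responders, outer_folds=2, inner_folds=2, seed=0)


def test_svm_nested_cv_chance_level_on_null_features():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(200, 5))
    y = np.repeat([0, 1], 100)
    bacc = svm_nested_cv(x, y, seed=1)
    assert 0.38 <= bacc <= 0.62


class TestPairedComparison:
    def test_textbook_paired_t(self):
        diffs = np.array([0.05, 0.08, 0.02, 0.06, 0.04])
        base = np.full(5, 0.7)
        stat, p, _ = paired_t_test(base + diffs, base)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        expected_p = 2 * stats.t.sf(abs(expected_t), df=4)
        assert stat == pytest.approx(expected_t, abs=1e-10)
        assert p == pytest.approx(expected_p, abs=1e-10)

    def test_identical_predictions_not_significant(self):
        y = np.repeat([0, 1], 10)
        pred = y.copy()
        folds = np.tile([0, 1, 2, 3, 4], 4)
        stat, p, sig = paired_comparison(pred, pred, y, fold_assignment=folds)
        assert stat == 0.0 and p == 1.0 and not sig

    def test_zero_variance_nonzero_difference_is_significant(self):
        y = np.tile(np.repeat([0, 1], 2), 5)
        perfect = y.copy()
        anti = 1 - y
        folds = np.repeat(np.arange(5), 4)
        stat, p, sig = paired_comparison(perfect, anti, y, fold_assignment=folds)
        assert sig and p < 1e-12 and stat == np.inf

    def test_requires_two_folds(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValidationError):
            paired_comparison(y, y, y, fold_assignment=np.zeros(4))

    def test_requires_fold_assignment(self):
        y = np.array([0, 1])
        with pytest.raises(ValidationError):
            paired_comparison(y, y, y)
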