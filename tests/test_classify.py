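"""Tests for ROC threshold analysis and the two-feature rule."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from sbpseg.classify import (
    DecisionRule2D,
    ROCResult,
    ROCThresholdClassifier,
    TwoFeatureRuleClassifier,
    confusion_stats,
    loo_accuracy,
    optimal_threshold,
    roc_curve,
    rule2d_evaluate,
)


def brute_force_threshold(roc: ROCResult) -> float:
    best = (np.inf, np.inf, None)
    for thr, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
        key = (np.sqrt(fpr**2 + (1 - tpr) ** 2), fpr)
        if key < best[:2]:
            best = (*key, thr)
    return best[2]


class TestROCCurve:
    def test_perfect_separation(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        roc = roc_curve(values, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.accuracy == 1.0
        assert roc.optimal_threshold == pytest.approx(6.5)  # separating gap midpoint

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], [True, True])

    def test_sweep_monotone_and_bounded(self, rng):
        values = rng.standard_normal(40)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_curve(values, labels)
        assert np.all(np.diff(roc.thresholds) > 0)
        assert np.all(np.diff(roc.tpr) <= 0) and np.all(np.diff(roc.fpr) <= 0)
        assert roc.tpr.min() >= 0 and roc.tpr.max() <= 1

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(50):
            n1, n0 = int(rng.integers(3, 20)), int(rng.integers(3, 20))
            values = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
            labels = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
            roc = roc_curve(values, labels)
            u = stats.mannwhitneyu(values[labels], values[~labels]).statistic
            assert roc.auc == pytest.approx(u / (n1 * n0), abs=1e-10)
            assert roc.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-10)

    def test_permuted_labels_auc_near_half(self, rng):
        values = rng.standard_normal(30)
        aucs = []
        for _ in range(500):
            labels = np.zeros(30, bool)
            labels[rng.choice(30, 12, replace=False)] = True
            aucs.append(roc_curve(values, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = np.abs(rng.standard_normal(30)) + 0.1
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        base = roc_curve(values, labels).auc
        assert roc_curve(np.log(values), labels).auc == pytest.approx(base)
        assert roc_curve(values**3, labels).auc == pytest.approx(base)

    def test_direction_less(self):
        values = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([1, 1, 0, 0], bool)  # positives have LOW values
        roc = roc_curve(values, labels, direction="less")
        assert roc.auc == pytest.approx(1.0)
        assert roc.accuracy == 1.0


class TestOptimalThreshold:
    def test_matches_brute_force(self, rng):
        for _ in range(30):
            values = rng.standard_normal(25)
            labels = rng.random(25) < 0.4
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            roc = roc_curve(values, labels)
            assert optimal_threshold(roc) == brute_force_threshold(roc)
            assert optimal_threshold(roc) in roc.thresholds

    def test_interior_point_beats_corners(self):
        roc = ROCResult(
            thresholds=np.array([0.0, 1.0, 2.0]),
            tpr=np.array([1.0, 0.9, 0.0]),
            fpr=np.array([1.0, 0.2, 0.0]),
            auc=0.85, optimal_threshold=np.nan,
            accuracy=np.nan, sensitivity=np.nan, specificity=np.nan,
        )
        assert optimal_threshold(roc) == 1.0

    def test_tie_prefers_lower_fpr(self):
        # both interior points at distance sqrt(.2^2+.2^2); pick FPR 0.2 one
        roc = ROCResult(
            thresholds=np.array([0.0, 1.0, 2.0, 3.0]),
            tpr=np.array([1.0, 1.0, 0.8, 0.0]),
            fpr=np.array([1.0, 0.2, 0.0, 0.0]),
            auc=np.nan, optimal_threshold=np.nan,
            accuracy=np.nan, sensitivity=np.nan, specificity=np.nan,
        )
        # distances: 1, .2, .2, 1 -> tie between thresholds 1.0 (fpr .2) and 2.0 (fpr 0)
        assert optimal_threshold(roc) == 2.0


class TestConfusionStats:
    def test_all_correct(self):
        acc, sens, spec, *_ = confusion_stats([1, 2, 9, 10], [0, 0, 1, 1], 5.0)
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_predicted_apneic_cohort_counts(self):
        values = np.arange(33, dtype=float) + 1
        labels = np.array([True] * 26 + [False] * 7)
        acc, sens, spec, tp, tn, fp, fn = confusion_stats(values, labels, 0.0)
        assert acc == pytest.approx(26 / 33)
        assert (tp, tn, fp, fn) == (26, 0, 7, 0)

    def test_identity(self, rng):
        values = rng.standard_normal(40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        acc, _, _, tp, tn, fp, fn = confusion_stats(values, labels, 0.3)
        assert acc == (tp + tn) / (tp + tn + fp + fn)
        assert tp + tn + fp + fn == 40


class TestRule2D:
    def test_low_low_is_non_apneic(self):
        rule = DecisionRule2D(threshold_L=100, threshold_A=20)
        assert not rule.predict([50], [10])[0]
        assert rule.predict([150], [10])[0]
        assert rule.predict([50], [30])[0]

    def test_infinite_thresholds_predict_everyone_negative(self):
        rule = DecisionRule2D(threshold_L=np.inf, threshold_A=np.inf)
        out = rule2d_evaluate([1, 500], [1, 99], [True, False], rule)
        assert not out["predictions"].any()
        assert out["sensitivity"] == 0.0 and out["specificity"] == 1.0

    def test_missing_features_skipped_with_warning(self, caplog):
        import logging

        rule = DecisionRule2D(threshold_L=10, threshold_A=10)
        with caplog.at_level(logging.WARNING, logger="sbpseg.classify"):
            out = rule2d_evaluate([1, np.nan, 20], [1, 2, 20], [False, False, True], rule)
        assert out["n_used"] == 2
        assert any("missing features" in r.message for r in caplog.records)

    def test_or_variant_more_conservative_negative(self):
        rule_and = DecisionRule2D(10, 10, "and_negative")
        rule_or = DecisionRule2D(10, 10, "or_negative")
        # high-L, low-A subject: AND-negative says apneic, OR-negative says not
        assert rule_and.predict([20], [5])[0]
        assert not rule_or.predict([20], [5])[0]


class TestLooAccuracy:
    def test_perfectly_separated(self):
        values = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        assert loo_accuracy(values, labels) == 1.0


class TestEstimators:
    def test_roc_threshold_classifier_fit_predict(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        est = ROCThresholdClassifier().fit(X, y)
        assert est.auc_ == pytest.approx(1.0)
        assert est.accuracy_ == 1.0
        assert np.array_equal(est.predict(X), y)
        assert np.all(est.decision_function(X[:3]) < 0)

    def test_two_feature_rule_classifier(self):
        X = np.array([[50, 5], [60, 6], [200, 5], [70, 40], [220, 50]], float)
        y = np.array([0, 0, 1, 1, 1])
        est = TwoFeatureRuleClassifier().fit(X, y)
        assert np.array_equal(est.predict(X), y)
        assert est.rule_.threshold_L < 200 and est.rule_.threshold_A < 40

    def test_sklearn_protocol(self):
        est = ROCThresholdClassifier(direction="less")
        assert clone(est).get_params() == est.get_params()
        est2 = TwoFeatureRuleClassifier(rule="or_negative")
        assert clone(est2).get_params()["rule"] == "or_negative"

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            ROCThresholdClassifier().predict([[1.0]])
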