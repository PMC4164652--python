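"""ROC threshold analysis and the combined two-feature screening rule.

Each quantifier (mean patch length ``<L>``, mean patch variance ``<s2>``,
normalized spectral peak ``A_max``) correlates positively with apnea
severity, so a subject is called apneic when the quantifier exceeds a
threshold.  The threshold is chosen from the ROC curve as the sweep point
with the smallest Euclidean distance to the perfect-classification corner
(FPR=0, TPR=1); ties go to the lower-FPR point, favouring specificity in a
screening context.  Accuracy is apparent accuracy, (TP + TN) / n — with
cohorts of a few dozen subjects that is the natural headline metric, and a
leave-one-out variant is available for an honesty check.

The two-feature rule combines ``<L>`` and ``A_max``: a subject is predicted
non-apneic only in the low-``<L>``, low-``A_max`` quadrant (both features at
or below their own ROC-optimal thresholds); anything else is called apneic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ROCResult",
    "DecisionRule2D",
    "roc_curve",
    "optimal_threshold",
    "confusion_stats",
    "rule2d_evaluate",
    "loo_accuracy",
    "ROCThresholdClassifier",
    "TwoFeatureRuleClassifier",
]

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    """Full threshold sweep for one feature (positive class = apneic)."""

    thresholds: np.ndarray  # ascending candidate thresholds
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class DecisionRule2D:
    """Predict apneic unless both features are at or below their thresholds."""

    threshold_L: float
    threshold_A: float
    rule: str = "and_negative"  # 'and_negative' (low-low quadrant) or 'or_negative'

    def predict(self, mean_L, a_max) -> np.ndarray:
        mean_L = np.asarray(mean_L, float)
        a_max = np.asarray(a_max, float)
        low_L = mean_L <= self.threshold_L
        low_A = a_max <= self.threshold_A
        if self.rule == "and_negative":
            negative = low_L & low_A
        elif self.rule == "or_negative":
            negative = low_L | low_A
        else:
            raise ValueError("rule must be 'and_negative' or 'or_negative'")
        return ~negative


def _validate_binary(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return values, labels


def roc_curve(feature_values, labels, direction: str = "greater") -> ROCResult:
    """Threshold sweep over midpoints between consecutive distinct values.

    ``direction='greater'`` classifies "apneic if value > threshold" (the
    default for all three quantifiers, which grow with severity); ``'less'``
    flips the comparison.  Sentinel thresholds below and above the data
    anchor the (1,1) and (0,0) ROC corners.  AUC is the trapezoidal area,
    equal to the Mann-Whitney U statistic normalized by ``n1 * n0``.
    """
    values, labels = _validate_binary(feature_values, labels)
    if direction == "less":
        return _flip(roc_curve(-values, labels, "greater"))
    if direction != "greater":
        raise ValueError("direction must be 'greater' or 'less'")
    distinct = np.unique(values)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], midpoints, [distinct[-1] + 1.0]])
    pos = values[labels]
    neg = values[~labels]
    # predictions: value > threshold
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])
    # thresholds ascend, so (fpr, tpr) descend from (1,1) to (0,0)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    opt = _optimal_from_sweep(thresholds, tpr, fpr)
    acc, sens, spec, *_ = confusion_stats(values, labels, opt)
    return ROCResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        optimal_threshold=opt, accuracy=acc, sensitivity=sens, specificity=spec,
    )


def _flip(roc: ROCResult) -> ROCResult:
    roc.thresholds = -roc.thresholds[::-1]
    roc.tpr = roc.tpr[::-1]
    roc.fpr = roc.fpr[::-1]
    roc.optimal_threshold = -roc.optimal_threshold
    return roc


def _optimal_from_sweep(thresholds, tpr, fpr) -> float:
    dist = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(dist == dist.min())
    if best.size > 1:  # ties: favour specificity (lower FPR)
        best = best[np.argsort(fpr[best], kind="stable")]
    return float(thresholds[best[0]])


def optimal_threshold(roc: ROCResult) -> float:
    """Sweep point minimizing the distance to the (FPR=0, TPR=1) corner."""
    return _optimal_from_sweep(roc.thresholds, roc.tpr, roc.fpr)


def confusion_stats(values, labels, threshold: float, direction: str = "greater"):
    """(accuracy, sensitivity, specificity, TP, TN, FP, FN) at a threshold."""
    values, labels = _validate_binary(values, labels)
    pred = values > threshold if direction == "greater" else values < threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    n = tp + tn + fp + fn
    return (
        (tp + tn) / n,
        tp / (tp + fn),
        tn / (tn + fp),
        tp, tn, fp, fn,
    )


def rule2d_evaluate(mean_L, a_max, labels, rule: DecisionRule2D) -> dict:
    """Apply the two-feature rule and report its confusion statistics.

    Subjects with a missing (NaN) feature are skipped with a logged warning.
    """
    mean_L = np.asarray(mean_L, dtype=float)
    a_max = np.asarray(a_max, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = np.isfinite(mean_L) & np.isfinite(a_max)
    if not ok.all():
        logger.warning("skipping %d subject(s) with missing features", int((~ok).sum()))
    mean_L, a_max, labels = mean_L[ok], a_max[ok], labels[ok]
    pred = rule.predict(mean_L, a_max)
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    n = tp + tn + fp + fn
    return {
        "predictions": pred,
        "accuracy": (tp + tn) / n if n else np.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "n_used": n,
    }


def loo_accuracy(values, labels, direction: str = "greater") -> float:
    """Leave-one-out accuracy of the ROC-optimal threshold rule."""
    values, labels = _validate_binary(values, labels)
    correct = 0
    for i in range(values.size):
        mask = np.ones(values.size, bool)
        mask[i] = False
        if labels[mask].all() or not labels[mask].any():
            continue
        roc = roc_curve(values[mask], labels[mask], direction)
        pred = values[i] > roc.optimal_threshold if direction == "greater" \
            else values[i] < roc.optimal_threshold
        correct += int(pred == labels[i])
    return correct / values.size


class ROCThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature screening classifier with a ROC-optimal threshold.

    Parameters
    ----------
    direction : {'greater', 'less'}, default 'greater'
        'greater' predicts apneic when the feature exceeds the threshold.

    Attributes
    ----------
    roc_ : ROCResult of the training sweep.
    threshold_ : float, the corner-distance-optimal threshold.
    auc_, accuracy_, sensitivity_, specificity_ : training metrics.
    classes_ : ndarray [0, 1]; 1 is the apneic (positive) class.
    """

    def __init__(self, direction: str = "greater"):
        self.direction = direction

    def _values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("ROCThresholdClassifier handles exactly one feature")
            X = X[:, 0]
        return X

    def fit(self, X, y) -> "ROCThresholdClassifier":
        values = self._values(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("ROCThresholdClassifier requires two classes")
        labels = y == self.classes_.max()
        self.roc_ = roc_curve(values, labels, self.direction)
        self.threshold_ = self.roc_.optimal_threshold
        self.auc_ = self.roc_.auc
        self.accuracy_ = self.roc_.accuracy
        self.sensitivity_ = self.roc_.sensitivity
        self.specificity_ = self.roc_.specificity
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        values = self._values(X)
        pred = values > self.threshold_ if self.direction == "greater" \
            else values < self.threshold_
        return np.where(pred, self.classes_.max(), self.classes_.min())

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        values = self._values(X)
        sign = 1.0 if self.direction == "greater" else -1.0
        return sign * (values - self.threshold_)


class TwoFeatureRuleClassifier(ClassifierMixin, BaseEstimator):
    """Combined (<L>, A_max) rule: non-apneic only in the low-low quadrant.

    ``fit`` learns one ROC-optimal threshold per column of the two-column
    input; ``predict`` applies the quadrant rule.

    Parameters
    ----------
    rule : {'and_negative', 'or_negative'}, default 'and_negative'
        'and_negative' calls a subject non-apneic only when *both* features
        are at or below their thresholds.
    """

    def __init__(self, rule: str = "and_negative"):
        self.rule = rule

    def fit(self, X, y) -> "TwoFeatureRuleClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("TwoFeatureRuleClassifier expects a (n, 2) feature matrix")
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("TwoFeatureRuleClassifier requires two classes")
        labels = y == self.classes_.max()
        rocs = [roc_curve(X[:, j], labels) for j in range(2)]
        self.rocs_ = rocs
        self.rule_ = DecisionRule2D(
            threshold_L=rocs[0].optimal_threshold,
            threshold_A=rocs[1].optimal_threshold,
            rule=self.rule,
        )
        self.n_features_in_ = 2
        report = rule2d_evaluate(X[:, 0], X[:, 1], labels, self.rule_)
        self.accuracy_ = report["accuracy"]
        self.sensitivity_ = report["sensitivity"]
        self.specificity_ = report["specificity"]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rule_")
        X = np.asarray(X, dtype=float)
        pred = self.rule_.predict(X[:, 0], X[:, 1])
        return np.where(pred, self.classes_.max(), self.classes_.min())
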