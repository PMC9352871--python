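"""Performance assessment of a selected feature subset.

The protocol: 20 independent repetitions of stratified 5-fold
cross-validation; within each repeat the confusion counts are pooled over
the five folds (every sample is predicted exactly once per repeat), then

* sensitivity = TP / (TP + FN),
* specificity = TN / (TN + FP),
* accuracy    = (TP + TN) / (TP + TN + FP + FN),

are computed from the totals pooled over all repeats, AUC is the mean of the
per-repeat pooled-score AUCs, and the 20 per-repeat accuracies form the
sample that the two-sample Kolmogorov-Smirnov test compares across
classifier variants.  Because each repeat scores every sample once, the
pooled ratios equal the mean of the per-repeat ratios exactly.

A frozen feature subset selected on one cohort can be re-evaluated on
another cohort (the GBM-to-LGG transfer pattern) with
:func:`transfer_evaluate`: features missing from the target are dropped and
reported, and the classifier is retrained within the target's CV folds — no
re-selection takes place.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import FeatureTable, subset_features
from .errors import DataError
from .fitness import FitnessSpec, make_classifier, predict_scores

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "auc_score",
    "repeated_cv_evaluate",
    "ks_compare",
    "transfer_evaluate",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EvaluationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    per_repeat_accuracies: tuple[float, ...]
    confusion_totals: dict = field(default_factory=dict)  # TP/FP/TN/FN pooled
    feature_subset: tuple[str, ...] = ()
    n_dropped_features: int = 0

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat_accuracies)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "per_repeat_accuracies": list(self.per_repeat_accuracies),
            "confusion_totals": dict(self.confusion_totals),
            "feature_subset": list(self.feature_subset),
            "n_dropped_features": self.n_dropped_features,
        }


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with positive class = 1.

    If ``y_true`` contains a single class the undefined ratio is returned as
    NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DataError("y_true and y_pred must be equal-length, non-empty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    if np.isnan(sens) or np.isnan(spec):
        warnings.warn(
            "y_true has a single class; sensitivity or specificity undefined",
            stacklevel=2,
        )
    acc = (tp + tn) / y_true.size
    return sens, spec, acc


def auc_score(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve — the probability that a random positive
    outscores a random negative, ties counted 1/2 (Mann-Whitney form)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise DataError("y_true and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise DataError("AUC undefined for single-class y_true")
    return float(roc_auc_score(y_true, scores))


def _pooled_report(
    tp: int, fp: int, tn: int, fn: int,
    per_repeat_acc: Sequence[float],
    per_repeat_auc: Sequence[float],
    subset: Sequence[str],
    n_dropped: int = 0,
) -> EvaluationReport:
    total = tp + fp + tn + fn
    return EvaluationReport(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / total,
        auc=float(np.mean(per_repeat_auc)),
        per_repeat_accuracies=tuple(float(a) for a in per_repeat_acc),
        confusion_totals={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        feature_subset=tuple(subset),
        n_dropped_features=n_dropped,
    )


def repeated_cv_evaluate(
    table: FeatureTable,
    feature_subset: Sequence[str],
    classifier_spec: FitnessSpec | None = None,
    n_repeats: int = 20,
    n_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified CV of one fixed feature subset.

    Each repeat uses a distinct fold seed derived from ``seed``; the report
    carries pooled confusion totals, mean metrics, per-repeat AUC mean, and
    the per-repeat accuracy sample used for KS model comparison.
    Deterministic for a fixed seed.
    """
    feature_subset = tuple(feature_subset)
    if not feature_subset:
        raise DataError("cannot evaluate an empty feature subset")
    spec = classifier_spec or FitnessSpec()
    sub = subset_features(table, feature_subset)
    sub.require_both_classes()
    X, y = sub.values, sub.labels
    seeds = np.random.SeedSequence(int(seed)).generate_state(n_repeats + 1)
    factory = make_classifier(
        spec.classifier_id, spec.params_dict, int(seeds[-1]) % _SEED_MOD
    )
    tp = fp = tn = fn = 0
    per_repeat_acc: list[float] = []
    per_repeat_auc: list[float] = []
    for r in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(seeds[r]) % _SEED_MOD,
        )
        y_pred = np.empty_like(y)
        y_score = np.empty(len(y), dtype=float)
        for train_idx, test_idx in skf.split(X, y):
            model = factory()
            model.fit(X[train_idx], y[train_idx])
            y_pred[test_idx] = model.predict(X[test_idx])
            y_score[test_idx] = predict_scores(model, X[test_idx])
        tp += int(np.sum((y == 1) & (y_pred == 1)))
        fn += int(np.sum((y == 1) & (y_pred == 0)))
        tn += int(np.sum((y == 0) & (y_pred == 0)))
        fp += int(np.sum((y == 0) & (y_pred == 1)))
        per_repeat_acc.append(float(np.mean(y_pred == y)))
        per_repeat_auc.append(auc_score(y, y_score))
    return _pooled_report(
        tp, fp, tn, fn, per_repeat_acc, per_repeat_auc, feature_subset
    )


def ks_compare(
    acc_a: Sequence[float], acc_b: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of accuracy samples.

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic two-sample distribution by default (``exact=True``
    switches to the exact small-sample computation).
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.size == 0 or acc_b.size == 0:
        raise DataError("KS comparison needs non-empty samples")
    result = stats.ks_2samp(acc_a, acc_b, method="exact" if exact else "asymp")
    return float(result.statistic), float(result.pvalue)


def transfer_evaluate(
    frozen_subset: Sequence[str],
    target: FeatureTable,
    classifier_spec: FitnessSpec | None = None,
    n_repeats: int = 20,
    n_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a subset selected elsewhere entirely within ``target``.

    No re-selection: the frozen names are intersected with the target's
    feature space (missing names dropped and counted) and the classifier is
    retrained per CV fold inside the target table.
    """
    frozen_subset = tuple(frozen_subset)
    if not frozen_subset:
        raise DataError("empty frozen subset")
    available = set(target.feature_names)
    present = [f for f in frozen_subset if f in available]
    n_dropped = len(frozen_subset) - len(present)
    if not present:
        raise DataError(
            "no frozen-subset feature exists in the target table"
        )
    if n_dropped:
        logger.warning(
            "transfer evaluation: %d of %d frozen features missing from "
            "target, evaluating the remaining %d",
            n_dropped, len(frozen_subset), len(present),
        )
    report = repeated_cv_evaluate(
        target, present, classifier_spec, n_repeats=n_repeats,
        n_folds=n_folds, seed=seed,
    )
    return EvaluationReport(
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        accuracy=report.accuracy,
        auc=report.auc,
        per_repeat_accuracies=report.per_repeat_accuracies,
        confusion_totals=report.confusion_totals,
        feature_subset=report.feature_subset,
        n_dropped_features=n_dropped,
    )
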