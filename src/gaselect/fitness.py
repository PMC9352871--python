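"""Wrapper fitness: cross-validated classifier accuracy on a feature mask.

The GA scores a chromosome (a binary feature mask) by the mean accuracy,
ACC-bar, of a classifier under repeated stratified k-fold cross-validation
restricted to the masked columns.  Three classifiers are supported:

* ``rf``  — random forest, 100 trees;
* ``svm`` — support vector machine with a radial-basis kernel, features
  standardized with train-fold statistics (RBF kernels are scale-sensitive;
  the tree models are not, so they see raw features);
* ``xgb`` — XGBoost classifier with library defaults.

Fold assignment is frozen per evaluator (derived from ``fold_seed`` only),
so fitness is a pure, memoizable function of the chromosome — which is what
makes elitism's best-fitness monotonicity exactly assertable and the cache
sound.  The all-zero chromosome has fitness 0 by definition: no classifier
can be trained on an empty feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .data import FeatureTable
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFIER_IDS",
    "FitnessSpec",
    "FitnessRecord",
    "FitnessEvaluator",
    "make_classifier",
    "evaluate_fitness",
]

CLASSIFIER_IDS = ("rf", "xgb", "svm")

_SEED_MOD = 2**31


def make_classifier(
    classifier_id: str,
    classifier_params: Mapping | None = None,
    seed: int = 0,
):
    """Return a zero-argument factory of unfitted estimators.

    Two factories built from the same seed produce identically-behaving
    estimators.  ``rf`` and ``xgb`` expose ``predict_proba`` and ``svm`` a
    decision margin, so all three support ROC computation downstream.
    """
    params = dict(classifier_params or {})
    seed = int(seed) % _SEED_MOD
    if classifier_id == "rf":
        params.setdefault("n_estimators", 100)
        params.setdefault("n_jobs", 1)

        def factory():
            return RandomForestClassifier(random_state=seed, **params)

    elif classifier_id == "svm":
        params.setdefault("kernel", "rbf")

        def factory():
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svc", SVC(random_state=seed, **params)),
                ]
            )

    elif classifier_id == "xgb":
        params.setdefault("n_jobs", 1)
        params.setdefault("verbosity", 0)

        def factory():
            return XGBClassifier(random_state=seed, **params)

    else:
        raise ConfigurationError(
            f"unknown classifier {classifier_id!r}; expected one of {CLASSIFIER_IDS}"
        )
    return factory


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 score: probability for rf/xgb, margin for svm."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass(frozen=True)
class FitnessSpec:
    """Defines the wrapper fitness function.

    ``n_repeats`` defaults to 2 inside the GA (cost control); the final
    evaluation protocol uses 20 repeats (see :mod:`gaselect.evaluation`).
    """

    classifier_id: str = "rf"
    classifier_params: tuple = ()  # items of a params mapping, hashable
    n_folds: int = 5
    n_repeats: int = 2
    fold_seed: int = 0
    classifier_seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier_id not in CLASSIFIER_IDS:
            raise ConfigurationError(
                f"unknown classifier {self.classifier_id!r}"
            )
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if isinstance(self.classifier_params, Mapping):
            object.__setattr__(
                self, "classifier_params", tuple(sorted(self.classifier_params.items()))
            )

    @property
    def params_dict(self) -> dict:
        return dict(self.classifier_params)

    def with_seeds(self, fold_seed: int, classifier_seed: int) -> "FitnessSpec":
        return replace(
            self,
            fold_seed=int(fold_seed) % _SEED_MOD,
            classifier_seed=int(classifier_seed) % _SEED_MOD,
        )


@dataclass(frozen=True)
class FitnessRecord:
    """Cached result of one chromosome evaluation (the ACC-bar of the
    roulette-selection formula)."""

    chromosome_key: str
    mean_accuracy: float
    per_fold_accuracies: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.per_fold_accuracies:
            mean = float(np.mean(self.per_fold_accuracies))
            if abs(mean - self.mean_accuracy) > 1e-12:
                raise ValueError("mean_accuracy inconsistent with folds")


def chromosome_key(bits: Sequence[int]) -> str:
    return "".join("1" if b else "0" for b in bits)


class FitnessEvaluator:
    """Memoized fitness function over a fixed candidate table.

    Folds are drawn once at construction from ``spec.fold_seed`` and reused
    for every chromosome, so repeated evaluation of the same mask is a cache
    hit and different masks are compared on identical resampling.
    """

    def __init__(self, table: FeatureTable, spec: FitnessSpec):
        table.require_both_classes()
        if spec.n_folds > min(table.class_counts):
            raise ConfigurationError(
                f"{spec.n_folds} folds but smallest class has "
                f"{min(table.class_counts)} samples"
            )
        self.table = table
        self.spec = spec
        self._factory = make_classifier(
            spec.classifier_id, spec.params_dict, spec.classifier_seed
        )
        y = table.labels
        self._folds: list[tuple[np.ndarray, np.ndarray]] = []
        for r in range(spec.n_repeats):
            skf = StratifiedKFold(
                n_splits=spec.n_folds,
                shuffle=True,
                random_state=(spec.fold_seed + r) % _SEED_MOD,
            )
            self._folds.extend(
                (tr, te) for tr, te in skf.split(np.zeros(len(y)), y)
            )
        self._cache: dict[str, FitnessRecord] = {}
        self.n_evaluations = 0  # cache misses, i.e. actual CV runs

    @property
    def n_candidates(self) -> int:
        return self.table.n_features

    def __call__(self, bits: Sequence[int]) -> FitnessRecord:
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.shape != (self.n_candidates,):
            raise ConfigurationError(
                f"chromosome length {bits.shape} does not match "
                f"{self.n_candidates} candidate features"
            )
        key = chromosome_key(bits)
        record = self._cache.get(key)
        if record is None:
            record = self._evaluate(bits, key)
            self._cache[key] = record
        return record

    def _evaluate(self, bits: np.ndarray, key: str) -> FitnessRecord:
        if not bits.any():
            # no features -> no trainable model; defined as fitness 0
            return FitnessRecord(key, 0.0, ())
        self.n_evaluations += 1
        X = self.table.values[:, bits.astype(bool)]
        y = self.table.labels
        accs = []
        try:
            for train_idx, test_idx in self._folds:
                model = self._factory()
                model.fit(X[train_idx], y[train_idx])
                pred = model.predict(X[test_idx])
                accs.append(float(np.mean(pred == y[test_idx])))
        except Exception:  # pragma: no cover - defensive
            logger.warning(
                "classifier failed on subset %s; fitness set to 0", key,
                exc_info=True,
            )
            return FitnessRecord(key, 0.0, ())
        return FitnessRecord(key, float(np.mean(accs)), tuple(accs))

    def cache_info(self) -> dict:
        return {"entries": len(self._cache), "evaluations": self.n_evaluations}


def evaluate_fitness(
    table: FeatureTable, chromosome: Sequence[int], spec: FitnessSpec
) -> FitnessRecord:
    """One-shot evaluation (builds a throwaway evaluator)."""
    return FitnessEvaluator(table, spec)(chromosome)
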