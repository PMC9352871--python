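"""Stage-1 feature pre-selection by gradient-boosted-tree gain importance.

A single XGBoost fit on the full table ranks features by their gain score —
the loss reduction a feature contributes across all tree splits.  Features
that never enter a split carry zero gain and are discarded by the default
``nonzero_gain`` policy; a ``top_k`` truncation policy is also available.
The surviving candidates become the search space of the GA wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import xgboost as xgb

from .data import FeatureTable
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BOOSTING_PARAMS",
    "ImportanceRanking",
    "fit_gain_importance",
    "select_stage1",
]

#: Boosting hyperparameters of the stage-1 model: logistic binary objective,
#: tree booster, learning rate (eta) 0.3, gamma 0, max depth 6, L2 penalty 1.
DEFAULT_BOOSTING_PARAMS: dict = {
    "objective": "binary:logistic",
    "booster": "gbtree",
    "eta": 0.3,
    "gamma": 0.0,
    "max_depth": 6,
    "lambda": 1.0,
}

#: Number of boosting rounds for the importance fit.
DEFAULT_N_ROUNDS = 100


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by descending gain (ties broken lexicographically).

    ``entries`` is a tuple of ``(feature_name, gain)`` pairs; features never
    used in a split have gain exactly 0 and sort after every positive-gain
    feature.
    """

    entries: tuple[tuple[str, float], ...]
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gains = [g for _, g in self.entries]
        if any(g < 0 for g in gains):
            raise ValueError("gains must be nonnegative")
        if any(gains[i] < gains[i + 1] for i in range(len(gains) - 1)):
            raise ValueError("entries must be sorted by non-increasing gain")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def gains(self) -> np.ndarray:
        return np.array([g for _, g in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\tgain\n")
            for name, gain in self.entries:
                fh.write(f"{name}\t{gain:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ImportanceRanking":
        entries = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("feature"):
                raise ConfigurationError(f"{path}: not a ranking TSV")
            for line in fh:
                name, gain = line.rstrip("\n").split("\t")
                entries.append((name, float(gain)))
        return cls(tuple(entries))


def fit_gain_importance(
    table: FeatureTable,
    params: Mapping | None = None,
    n_rounds: int = DEFAULT_N_ROUNDS,
    seed: int = 0,
) -> ImportanceRanking:
    """Fit one boosted ensemble on the whole table and rank features by gain.

    Deterministic for a fixed ``seed`` and input (single-threaded fit).
    Raises :class:`DataError` if the labels are constant.
    """
    table.require_both_classes()
    merged = {**DEFAULT_BOOSTING_PARAMS, **dict(params or {})}
    merged.setdefault("seed", int(seed))
    merged.setdefault("nthread", 1)
    dtrain = xgb.DMatrix(
        table.values,
        label=table.labels,
        feature_names=list(table.feature_names),
    )
    booster = xgb.train(merged, dtrain, num_boost_round=int(n_rounds))
    scores = booster.get_score(importance_type="gain")
    entries = sorted(
        ((name, float(scores.get(name, 0.0))) for name in table.feature_names),
        key=lambda item: (-item[1], item[0]),
    )
    return ImportanceRanking(tuple(entries), model_params=dict(merged))


def select_stage1(
    ranking: ImportanceRanking,
    policy: str = "nonzero_gain",
    k: int | None = None,
) -> tuple[str, ...]:
    """Apply a selection policy to a gain ranking.

    ``nonzero_gain`` keeps every feature with gain > 0, optionally capped at
    the top ``k``; ``top_k`` keeps the first ``min(k, available)`` entries.
    """
    if len(ranking) == 0:
        raise ConfigurationError("empty importance ranking")
    if policy == "nonzero_gain":
        selected = tuple(n for n, g in ranking.entries if g > 0)
        if not selected:
            logger.warning(
                "all gains are zero: stage-1 selected no features "
                "(the GA stage will refuse to start)"
            )
        if k is not None:
            if k <= 0:
                raise ConfigurationError(f"cap k must be positive, got {k}")
            selected = selected[:k]
        return selected
    if policy == "top_k":
        if k is None or k <= 0:
            raise ConfigurationError(f"top_k policy needs k >= 1, got {k}")
        return ranking.names[:k]
    raise ConfigurationError(f"unknown stage-1 policy {policy!r}")
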