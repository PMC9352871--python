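"""Feature-table I/O and alignment.

The :class:`FeatureTable` is the exchange object every other module consumes:
a dense numeric matrix of radiomics features (rows = patients/samples,
columns = named features) together with a binary phenotype label per sample
(1 = positive class, e.g. MGMT promoter methylated; 0 = negative).

Contracts enforced here so downstream code can assume them:

* no duplicate sample ids or feature names,
* every value finite (rows with missing cells are dropped at load time,
  never imputed),
* both label classes present (stratified cross-validation needs this).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "subset_features",
    "align_feature_spaces",
]


@dataclass(frozen=True)
class FeatureTable:
    """Named numeric feature matrix with binary labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique, ordered sample identifiers (one per row).
    feature_names : sequence of str
        Unique, ordered feature names (one per column).
    values : ndarray of shape (n_samples, n_features)
        Finite float matrix.
    labels : ndarray of shape (n_samples,)
        Binary labels; 1 marks the positive class.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(
            self, "feature_names", tuple(str(f) for f in self.feature_names)
        )
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        n, d = values.shape
        if len(self.sample_ids) != n or labels.shape != (n,):
            raise DataError(
                f"inconsistent sample dimensions: {len(self.sample_ids)} ids, "
                f"{n} rows, {labels.shape[0]} labels"
            )
        if len(self.feature_names) != d:
            raise DataError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if len(set(self.feature_names)) != d:
            raise DataError("duplicate feature names")
        if not np.all(np.isfinite(values)):
            raise DataError("non-finite values in feature matrix")
        if not np.isin(labels, (0, 1)).all():
            raise DataError("labels must be 0/1")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        pos = int(self.labels.sum())
        return self.n_samples - pos, pos

    def require_both_classes(self) -> None:
        neg, pos = self.class_counts
        if neg < 2 or pos < 2:
            raise DataError(
                f"need at least 2 samples per class, got {pos} positive / "
                f"{neg} negative"
            )

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown feature name: {exc.args[0]!r}") from None

    def sorted_by_sample_id(self) -> "FeatureTable":
        """Canonical row order (lexicographic sample id); makes downstream
        fold assignment invariant to input row order."""
        order = np.argsort(np.array(self.sample_ids, dtype=object))
        return FeatureTable(
            tuple(self.sample_ids[i] for i in order),
            self.feature_names,
            self.values[order],
            self.labels[order],
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )
        df.index.name = "sample_id"
        df[label_column] = self.labels
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        positive_label: object = 1,
    ) -> "FeatureTable":
        """Build from a DataFrame whose index holds sample ids."""
        if label_column not in df.columns:
            raise ConfigurationError(f"label column {label_column!r} not found")
        raw_labels = df[label_column]
        feat = df.drop(columns=[label_column]).apply(pd.to_numeric, errors="coerce")
        keep = feat.notna().all(axis=1) & raw_labels.notna()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "dropped %d sample(s) with missing values", n_dropped
            )
            feat, raw_labels = feat[keep], raw_labels[keep]
        labels = (raw_labels.astype(str) == str(positive_label)).to_numpy(int)
        table = cls(
            tuple(str(i) for i in feat.index),
            tuple(str(c) for c in feat.columns),
            feat.to_numpy(float),
            labels,
        )
        table.require_both_classes()
        return table


def read_feature_table(
    path,
    label_column: str,
    positive_label: object = 1,
    id_column: str | None = None,
) -> FeatureTable:
    """Read a CSV feature table (header row mandatory, UTF-8).

    Sample ids come from ``id_column``, or from the first column by default.
    Label values equal to ``positive_label`` (string comparison) map to 1,
    all others to 0.  Rows with any missing value are dropped with a logged
    warning.
    """
    df = pd.read_csv(
        path,
        dtype={0: str} if id_column is None else None,
        float_precision="round_trip",
    )
    if id_column is None:
        id_column = df.columns[0]
    elif id_column not in df.columns:
        raise ConfigurationError(f"id column {id_column!r} not found")
    if label_column not in df.columns:
        raise ConfigurationError(f"label column {label_column!r} not found")
    df = df.set_index(id_column)
    return FeatureTable.from_dataframe(df, label_column, positive_label)


def write_feature_table(
    table: FeatureTable, path, label_column: str = "label"
) -> None:
    """Write a CSV that :func:`read_feature_table` round-trips exactly
    (full float precision)."""
    df = table.to_dataframe(label_column)
    df.to_csv(path, float_format="%.17g")


def subset_features(
    table: FeatureTable,
    names: Iterable[str],
    allow_empty: bool = False,
) -> FeatureTable:
    """Project onto the requested columns, in the requested order.

    Samples and labels are unchanged.  Unknown names raise ``KeyError``;
    an empty selection raises :class:`ConfigurationError` unless
    ``allow_empty`` is set.
    """
    names = list(names)
    if not names:
        if allow_empty:
            return FeatureTable(
                table.sample_ids,
                (),
                np.empty((table.n_samples, 0)),
                table.labels,
            )
        raise ConfigurationError("empty feature subset (pass allow_empty=True to permit)")
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate names in feature subset")
    idx = table.feature_index(names)
    return FeatureTable(
        table.sample_ids, tuple(names), table.values[:, idx], table.labels
    )


def align_feature_spaces(
    source: FeatureTable, target: FeatureTable
) -> tuple[FeatureTable, FeatureTable]:
    """Restrict both tables to their common feature names, in source order.

    Used when a feature subset selected on one cohort (e.g. GBM) is applied
    to another (e.g. LGG) whose extraction produced a different feature set.
    """
    if source.n_features == 0 or target.n_features == 0:
        raise DataError("cannot align an empty feature table")
    target_set = set(target.feature_names)
    common = [f for f in source.feature_names if f in target_set]
    if not common:
        raise DataError("feature spaces are disjoint: no common feature names")
    dropped_source = source.n_features - len(common)
    dropped_target = target.n_features - len(common)
    if dropped_source or dropped_target:
        logger.info(
            "aligned feature spaces on %d common features (dropped %d from "
            "source, %d from target)",
            len(common), dropped_source, dropped_target,
        )
    return subset_features(source, common), subset_features(target, common)
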