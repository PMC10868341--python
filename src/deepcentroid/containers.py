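"""Core in-memory containers: feature matrices and binary label vectors.

A :class:`FeatureMatrix` is the unit of all I/O — a dense samples-by-features
numeric table with unique sample IDs and unique feature names. A
:class:`LabelVector` carries the binary class labels (1 = positive class)
aligned to sample IDs. Matrices and labels from separate files are joined by
sample ID with :func:`align` before any model sees them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _find_duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class FeatureMatrix:
    """Dense samples × features numeric matrix with row/column identifiers.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    feature_names
        Unique feature identifiers, one per column.
    values
        Numeric matrix of shape ``(n_samples, n_features)``. Stored as
        float64; must be finite after any load-time imputation policy.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} does not match {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"column count {p} does not match {len(self.feature_names)} feature names"
            )
        dup_s = _find_duplicates(list(self.sample_ids))
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s}")
        dup_f = _find_duplicates(list(self.feature_names))
        if dup_f:
            raise ValueError(f"duplicate feature names: {dup_f}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=np.float64),
        )

    def subset_samples(self, ids: list[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return FeatureMatrix(list(ids), list(self.feature_names), self.values[idx])


@dataclass
class LabelVector:
    """Binary labels (1 = positive class) aligned to sample IDs."""

    sample_ids: list[str]
    labels: np.ndarray
    positive_class_name: str = "positive"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must align 1:1 with sample_ids")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: list[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return LabelVector(list(ids), self.labels[idx], self.positive_class_name)


def align(
    matrix: FeatureMatrix, labels: LabelVector, min_per_class: int = 2
) -> tuple[FeatureMatrix, LabelVector]:
    """Inner-join a matrix and a label vector on sample ID.

    Samples present in only one of the two are dropped (logged). Training
    requires at least ``min_per_class`` samples in each class after the join.
    """
    label_pos = {s: i for i, s in enumerate(labels.sample_ids)}
    shared = [s for s in matrix.sample_ids if s in label_pos]
    dropped = (matrix.n_samples - len(shared)) + (labels.n_samples - len(shared))
    if dropped:
        logger.info("align: dropped %d samples not present in both inputs", dropped)
    if not shared:
        raise ValueError("matrix and labels share no sample IDs")
    m = matrix.subset_samples(shared)
    lv = labels.subset(shared)
    n_pos = int(lv.labels.sum())
    n_neg = len(shared) - n_pos
    if min(n_pos, n_neg) < min_per_class:
        raise ValueError(
            f"need at least {min_per_class} samples per class after join; "
            f"got {n_pos} positive / {n_neg} negative"
        )
    return m, lv
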