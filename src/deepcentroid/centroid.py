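"""Nearest-centroid base classifier and the pluggable base-classifier contract.

The base learner of the cascade is the plain (unshrunken) nearest-centroid
classifier: fit computes the per-class mean vector over the samples of each
class, and a sample is scored by the *signed* distance difference

    score(x) = d(x, centroid_neg) - d(x, centroid_pos)

so that a positive score means the sample sits nearer the positive centroid.
The signed scalar is what feeds the next cascade layer. Predicted label is 1
iff score > 0; an exact tie scores 0 and predicts negative (deterministic,
conservative for case/control screening).

Distances: Euclidean by default (the data are z-scored upstream); a
correlation distance (1 - Pearson r) is available but non-default.

Other learners (SVM, random forest, ...) can stand in as base classifiers by
implementing the same ``fit`` / ``decision_scores`` surface; a thin wrapper
around any scikit-learn classifier is provided for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .scanning import FeatureSet


class BaseClassifier(Protocol):
    """Contract every base learner must satisfy.

    ``fit`` learns state from a sub-matrix restricted to one feature set;
    ``decision_scores`` returns one finite real score per sample, higher
    meaning more positive; the induced hard label is 1 iff score > 0.
    """

    def fit(self, X_sub: np.ndarray, y: np.ndarray) -> "BaseClassifier": ...

    def decision_scores(self, X_sub: np.ndarray) -> np.ndarray: ...


def _euclidean(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum((X - c) ** 2, axis=1))


def _correlation(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    # 1 - Pearson r between each row and the centroid; degenerate rows -> r = 0
    Xc = X - X.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(cc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ cc / np.where(denom > 0, denom, 1.0), 0.0)
    return 1.0 - r


_DISTANCE_FUNCS = {"euclidean": _euclidean, "correlation": _correlation}


@dataclass
class CentroidModel:
    """Fitted per-class centroids over one feature set.

    ``val_mcc`` is populated only after out-of-bag evaluation by the cascade.
    """

    feature_set: FeatureSet
    centroid_pos: np.ndarray = field(repr=False)
    centroid_neg: np.ndarray = field(repr=False)
    distance: str = "euclidean"
    val_mcc: float | None = None

    def __post_init__(self) -> None:
        self.centroid_pos = np.asarray(self.centroid_pos, dtype=np.float64)
        self.centroid_neg = np.asarray(self.centroid_neg, dtype=np.float64)
        k = self.feature_set.size
        if self.centroid_pos.shape != (k,) or self.centroid_neg.shape != (k,):
            raise ValueError("centroid vectors must match the feature set length")
        if not (np.all(np.isfinite(self.centroid_pos)) and np.all(np.isfinite(self.centroid_neg))):
            raise ValueError("centroid vectors must be finite")
        if self.distance not in _DISTANCE_FUNCS:
            raise ValueError(f"unknown distance {self.distance!r}")


def fit_centroid(
    X_sub: np.ndarray, y: np.ndarray, feature_set: FeatureSet, distance: str = "euclidean"
) -> CentroidModel:
    """Fit per-class centroid vectors on a sub-matrix restricted to one feature set.

    ``X_sub`` has one column per member of ``feature_set`` (in set order); the
    centroid of each class is the per-feature mean over that class's samples.
    """
    X_sub = np.asarray(X_sub, dtype=np.float64)
    y = np.asarray(y)
    if X_sub.shape[1] != feature_set.size:
        raise ValueError(
            f"X_sub has {X_sub.shape[1]} columns, feature set has {feature_set.size}"
        )
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise ValueError("fit_centroid requires at least one sample of each class")
    return CentroidModel(
        feature_set=feature_set,
        centroid_pos=X_sub[pos].mean(axis=0),
        centroid_neg=X_sub[neg].mean(axis=0),
        distance=distance,
    )


def centroid_distances(model: CentroidModel, X_sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances (d_pos, d_neg) from each sample to the two centroids."""
    X_sub = np.asarray(X_sub, dtype=np.float64)
    if X_sub.ndim != 2 or X_sub.shape[1] != model.feature_set.size:
        raise ValueError(
            f"X_sub must have {model.feature_set.size} columns, got shape {X_sub.shape}"
        )
    d = _DISTANCE_FUNCS[model.distance]
    return d(X_sub, model.centroid_pos), d(X_sub, model.centroid_neg)


def score_centroid(model: CentroidModel, X_sub: np.ndarray) -> np.ndarray:
    """Signed score d(x, centroid_neg) - d(x, centroid_pos); positive ⇒ nearer positive."""
    d_pos, d_neg = centroid_distances(model, X_sub)
    return d_neg - d_pos


def predict_centroid(model: CentroidModel, X_sub: np.ndarray) -> np.ndarray:
    """Hard labels: 1 iff score > 0; an exact tie predicts negative."""
    return (score_centroid(model, X_sub) > 0).astype(np.int64)


class NearestCentroidBase:
    """Nearest-centroid learner under the :class:`BaseClassifier` contract."""

    def __init__(self, feature_set: FeatureSet, distance: str = "euclidean"):
        self.feature_set = feature_set
        self.distance = distance
        self.model: CentroidModel | None = None

    def fit(self, X_sub: np.ndarray, y: np.ndarray) -> "NearestCentroidBase":
        self.model = fit_centroid(X_sub, y, self.feature_set, self.distance)
        return self

    def decision_scores(self, X_sub: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before scoring")
        return score_centroid(self.model, X_sub)


class SklearnBase:
    """Adapter putting any scikit-learn binary classifier behind the contract.

    Used only for benchmarking alternative base learners; scores are shifted
    decision functions (or probability margins) so that label = 1 iff score > 0.
    """

    def __init__(self, feature_set: FeatureSet, estimator):
        self.feature_set = feature_set
        self.estimator = estimator

    def fit(self, X_sub: np.ndarray, y: np.ndarray) -> "SklearnBase":
        self.estimator.fit(X_sub, y)
        return self

    def decision_scores(self, X_sub: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X_sub), dtype=np.float64)
        proba = np.asarray(est.predict_proba(X_sub), dtype=np.float64)
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        return proba[:, pos_col] - 0.5


def make_base_classifier(
    name: str, feature_set: FeatureSet, distance: str = "euclidean", seed: int = 0
):
    """Factory for the pluggable base classifiers.

    ``nearest_centroid`` (default) is native; ``random_forest`` and ``svm``
    wrap scikit-learn estimators for ablation-style benchmarking.
    """
    if name == "nearest_centroid":
        return NearestCentroidBase(feature_set, distance)
    if name == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return SklearnBase(
            feature_set, RandomForestClassifier(n_estimators=50, random_state=seed)
        )
    if name == "svm":
        from sklearn.svm import SVC

        return SklearnBase(feature_set, SVC(kernel="linear", random_state=seed))
    raise ValueError(f"unknown base classifier {name!r}")
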