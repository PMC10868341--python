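"""Final-stage prediction and feature-importance ranking.

Prediction propagates new samples through every retained cascade layer with
the same score-augmentation scheme used in training, then lets each surviving
classifier of the last layer cast one hard vote. The fraction of positive
votes is reported as the positive-class probability; the hard label is 1 iff
that fraction exceeds 0.5 (an exact tie predicts negative).

Feature importance follows the idea that genes belonging to high-performing
base classifiers matter. A set-level score alone (e.g. the mean OOB MCC of the
classifiers containing a feature) dilutes away at realistic set sizes — each
set carries 10–200 features, so one gene moves its set's MCC very little.
Importance therefore combines the classifier's quality with the gene's own
contribution inside it: the absolute between-class centroid separation on that
feature, weighted by the classifier's OOB MCC, averaged over the surviving
first-layer classifiers containing the feature. Only first-layer classifiers
are used — deeper layers operate on derived score columns that no longer
correspond to original features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeModel, zscore_apply
from .containers import FeatureMatrix


@dataclass
class PredictionResult:
    """Per-sample vote fraction and hard label from the final cascade layer."""

    sample_ids: list[str]
    probability_positive: np.ndarray
    label: np.ndarray
    n_voters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "probability_positive": self.probability_positive,
                "predicted_label": self.label,
            }
        )


def _assemble_input(
    model: CascadeModel, X_new: FeatureMatrix, X2_new: FeatureMatrix | None
) -> np.ndarray:
    """Build the normalized full-width matrix the cascade was trained on.

    Only the columns the model actually references (layer-1 feature sets and
    re-injected columns) must be present in the new data; they are located by
    name and standardized with the stored training statistics.
    """
    lookup: dict[str, np.ndarray] = {
        name: X_new.values[:, j] for j, name in enumerate(X_new.feature_names)
    }
    if X2_new is not None:
        if list(X2_new.sample_ids) != list(X_new.sample_ids):
            raise ValueError("secondary matrix must carry the same sample IDs in order")
        for j, name in enumerate(X2_new.feature_names):
            key = name if name not in lookup else f"omics2|{name}"
            lookup.setdefault(key, X2_new.values[:, j])

    required = model.required_feature_names()
    missing = [name for name in required if name not in lookup]
    if missing:
        raise ValueError(
            f"{len(missing)} required features missing from input: {missing[:10]}"
        )
    name_to_col = {name: i for i, name in enumerate(model.feature_names)}
    Xfull = np.zeros((X_new.n_samples, len(model.feature_names)))
    cols = np.array([name_to_col[name] for name in required], dtype=np.int64)
    raw = np.column_stack([lookup[name] for name in required])
    mean = model.norm_stats.mean[cols]
    sd = np.where(model.norm_stats.sd[cols] > 0, model.norm_stats.sd[cols], 1.0)
    Z = (raw - mean) / sd
    Z[:, model.norm_stats.sd[cols] == 0] = 0.0
    Xfull[:, cols] = Z
    return Xfull


def predict(
    model: CascadeModel, X_new: FeatureMatrix, X2_new: FeatureMatrix | None = None
) -> PredictionResult:
    """Propagate samples through the cascade and majority-vote the last layer."""
    Xn = _assemble_input(model, X_new, X2_new)
    X_final = model.forward(Xn)
    final = model.final_layer
    votes = np.zeros(X_new.n_samples)
    for lc in final.classifiers:
        votes += lc.base.decision_scores(X_final[:, lc.feature_set.indices]) > 0
    n_voters = len(final.classifiers)
    proba = votes / n_voters
    return PredictionResult(
        sample_ids=list(X_new.sample_ids),
        probability_positive=proba,
        label=(proba > 0.5).astype(np.int64),
        n_voters=n_voters,
    )


def rank_important_features(model: CascadeModel, top_k: int = 50) -> pd.DataFrame:
    """Rank original features by their contribution to high-performing base classifiers.

    For every surviving first-layer classifier, each member feature is
    credited with ``val_mcc * |centroid_pos - centroid_neg|`` on that feature
    (the classifier's OOB quality times the gene's own between-class
    separation inside it); a feature's importance is the mean credit over the
    surviving classifiers containing it. For non-centroid base learners the
    separation term is unavailable and the credit falls back to ``val_mcc``
    alone.

    Returns the ``top_k`` rows of a table with columns ``feature_name``,
    ``importance`` and ``n_classifiers_containing``, sorted by descending
    importance (ties broken by name for determinism). Features contained in no
    surviving classifier do not appear.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    first = model.layers[0]
    p = len(model.feature_names)
    sums = np.zeros(p)
    counts = np.zeros(p, dtype=np.int64)
    for lc in first.classifiers:
        idx = lc.feature_set.indices
        base = lc.base
        if hasattr(base, "model") and base.model is not None:
            sep = np.abs(base.model.centroid_pos - base.model.centroid_neg)
            sums[idx] += lc.val_mcc * sep
        else:
            sums[idx] += lc.val_mcc
        counts[idx] += 1
    seen = np.flatnonzero(counts)
    rows = [
        (model.feature_names[j], sums[j] / counts[j], int(counts[j])) for j in seen
    ]
    table = pd.DataFrame(rows, columns=["feature_name", "importance", "n_classifiers_containing"])
    table = table.sort_values(
        ["importance", "feature_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(top_k)
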