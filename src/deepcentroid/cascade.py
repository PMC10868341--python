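"""Cascade learning engine.

Each cascade layer trains one base classifier per feature set, each on its own
balanced with-replacement resample of the training samples; the samples a
classifier never drew form its out-of-bag (OOB) validation set. Classifiers
whose OOB MCC falls at or below the prune threshold (default 0) are removed.
The surviving classifiers' signed scores become new feature columns which —
together with the re-injected scanned original features, so deeper layers keep
seeing fresh raw information — form the input of the next layer. Layer-level
performance is the MCC of the OOB majority vote (every sample is voted on only
by classifiers for which it is out-of-bag); training stops when this stops
improving, and the model keeps the best prefix of layers.

Randomness is derived from the single root seed through ``numpy``
``SeedSequence`` spawn keys, one stream per (stage, layer), so fits are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .centroid import NearestCentroidBase, centroid_distances, make_base_classifier
from .config import RunConfig
from .containers import FeatureMatrix, LabelVector, align
from .metrics import mcc_score
from .scanning import (
    FeatureSet,
    ScanPlan,
    gene_set_scan,
    random_scan,
    sliding_window_scan,
)

logger = logging.getLogger(__name__)

_MAX_RESAMPLE_RETRIES = 100


# ---------------------------------------------------------------------------
# z-score normalization (training statistics only)

@dataclass
class NormStats:
    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(X: np.ndarray) -> NormStats:
    """Per-feature mean and population standard deviation (ddof=0)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("z-score fitting requires at least 2 samples")
    return NormStats(mean=X.mean(axis=0), sd=X.std(axis=0))


def zscore_apply(stats: NormStats, X: np.ndarray) -> np.ndarray:
    """Standardize with training statistics; constant training columns map to 0."""
    X = np.asarray(X, dtype=np.float64)
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    Z = (X - stats.mean) / sd
    Z[:, stats.sd == 0] = 0.0
    return Z


def zscore_fit_apply(X: np.ndarray) -> tuple[np.ndarray, NormStats]:
    stats = zscore_fit(X)
    return zscore_apply(stats, X), stats


# ---------------------------------------------------------------------------
# balanced resampling

@dataclass
class ResampleSplit:
    """A with-replacement training draw and its out-of-bag complement.

    ``train_indices`` is a multiset (repeats allowed); ``oob_indices`` are the
    sample indices never drawn, used as the classifier's validation set.
    """

    train_indices: np.ndarray
    oob_indices: np.ndarray


def resample_balanced(
    y: np.ndarray,
    coefficient: float = 0.65,
    rng: np.random.Generator | int | None = None,
    coefficient_class: str = "minority",
) -> ResampleSplit:
    """Draw ``len(y)`` samples with replacement, pushing class composition toward balance.

    ``round(coefficient * n)`` draws come from the anchor class (the minority
    class by default, tie broken toward the positive class; or the positive
    class when ``coefficient_class='positive'``) and the rest from the other
    class. Redraws (bounded) if the out-of-bag set would be empty or a class
    were missing from the draw.
    """
    y = np.asarray(y)
    n = len(y)
    if not (0.0 < coefficient < 1.0):
        raise ValueError("coefficient must be in (0, 1)")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    if coefficient_class == "positive":
        anchor, other = pos_idx, neg_idx
    else:  # minority; tie -> positive
        anchor, other = (
            (pos_idx, neg_idx) if len(pos_idx) <= len(neg_idx) else (neg_idx, pos_idx)
        )
    k = int(round(coefficient * n))
    k = min(max(k, 1), n - 1)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for _ in range(_MAX_RESAMPLE_RETRIES):
        train = np.concatenate(
            [rng.choice(anchor, size=k, replace=True), rng.choice(other, size=n - k, replace=True)]
        )
        oob = np.setdiff1d(np.arange(n), train)
        if oob.size > 0 and y[train].min() == 0 and y[train].max() == 1:
            return ResampleSplit(train_indices=train, oob_indices=oob)
    raise RuntimeError(
        f"could not draw a valid resample in {_MAX_RESAMPLE_RETRIES} tries; "
        "the dataset is pathologically small"
    )


# ---------------------------------------------------------------------------
# layers

@dataclass
class LayerClassifier:
    """One surviving base classifier: fitted state, its OOB MCC, and its split."""

    base: object
    val_mcc: float
    split: ResampleSplit | None = None

    @property
    def feature_set(self) -> FeatureSet:
        return self.base.feature_set


@dataclass
class LayerState:
    layer_index: int
    classifiers: list[LayerClassifier]
    val_mcc: float
    n_trained: int
    n_pruned: int


def train_layer(
    X_layer: np.ndarray,
    y: np.ndarray,
    feature_sets: list[FeatureSet],
    config: RunConfig,
    rng: np.random.Generator,
) -> LayerState:
    """Train one cascade layer: one base classifier per feature set.

    Each classifier gets its own balanced resample; its OOB MCC decides
    pruning. The layer's validation MCC is the MCC of the OOB majority vote
    over all samples that are out-of-bag for at least one survivor.
    """
    n = X_layer.shape[0]
    survivors: list[LayerClassifier] = []
    votes_pos = np.zeros(n)
    votes_tot = np.zeros(n)
    for fs in feature_sets:
        if fs.indices.max() >= X_layer.shape[1]:
            raise ValueError(
                f"feature set {fs.set_id} references column {fs.indices.max()} "
                f"outside the layer input of width {X_layer.shape[1]}"
            )
        clf_seed = int(rng.integers(2**31))
        split = resample_balanced(
            y, config.sampling_coefficient, rng, config.coefficient_class
        )
        base = make_base_classifier(
            config.base_classifier, fs, config.distance, seed=clf_seed
        )
        base.fit(X_layer[np.ix_(split.train_indices, fs.indices)], y[split.train_indices])
        oob = split.oob_indices
        oob_pred = (base.decision_scores(X_layer[np.ix_(oob, fs.indices)]) > 0).astype(np.int64)
        m = mcc_score(y[oob], oob_pred)
        if m > config.prune_threshold:
            survivors.append(LayerClassifier(base=base, val_mcc=float(m), split=split))
            votes_pos[oob] += oob_pred
            votes_tot[oob] += 1
    if not survivors:
        raise RuntimeError(
            f"all {len(feature_sets)} base classifiers were pruned at "
            f"OOB MCC threshold {config.prune_threshold}; no layer survives"
        )
    voted = votes_tot > 0
    layer_pred = (votes_pos[voted] / votes_tot[voted]) > 0.5
    layer_mcc = mcc_score(y[voted], layer_pred.astype(np.int64))
    return LayerState(
        layer_index=0,  # assigned by fit_cascade
        classifiers=survivors,
        val_mcc=float(layer_mcc),
        n_trained=len(feature_sets),
        n_pruned=len(feature_sets) - len(survivors),
    )


def layer_scores(layer: LayerState, X_layer: np.ndarray, score_mode: str = "signed") -> np.ndarray:
    """Score columns produced by a layer's surviving classifiers, in training order.

    ``signed`` mode emits one column per classifier (d_neg - d_pos);
    ``two_distance`` emits the two raw centroid distances per classifier.
    """
    cols = []
    for lc in layer.classifiers:
        X_sub = X_layer[:, lc.feature_set.indices]
        if score_mode == "two_distance" and isinstance(lc.base, NearestCentroidBase):
            d_pos, d_neg = centroid_distances(lc.base.model, X_sub)
            cols.extend([d_pos, d_neg])
        else:
            cols.append(lc.base.decision_scores(X_sub))
    return np.column_stack(cols)


def augment_features(
    layer: LayerState,
    X_layer: np.ndarray,
    reinjected: np.ndarray | None,
    score_mode: str = "signed",
) -> np.ndarray:
    """Next-layer input: [survivor score columns | re-injected scan columns]."""
    scores = layer_scores(layer, X_layer, score_mode)
    if reinjected is None or reinjected.shape[1] == 0:
        return scores
    if reinjected.shape[0] != scores.shape[0]:
        raise ValueError("re-injected columns must have one row per sample")
    return np.hstack([scores, reinjected])


def _deep_layer_sets(
    width: int, config: RunConfig, rng: np.random.Generator
) -> list[FeatureSet]:
    """Random feature sets over an augmented layer input, same size law clamped to width."""
    smax = min(config.set_size_max, width)
    smin = min(config.set_size_min, smax)
    sets = []
    for k in range(config.n_feature_sets):
        size = int(rng.integers(smin, smax + 1))
        sets.append(FeatureSet(k, rng.choice(width, size=size, replace=False), "random"))
    return sets


# ---------------------------------------------------------------------------
# the full cascade

@dataclass
class CascadeModel:
    """A fitted cascade: retained layers plus everything needed to replay them."""

    layers: list[LayerState]
    scan_plan: ScanPlan
    config: RunConfig
    stop_reason: str
    norm_stats: NormStats
    feature_names: list[str]
    n_primary_features: int
    reinject_cols: np.ndarray
    positive_class_name: str = "positive"
    layer_log: list[dict] = field(default_factory=list, repr=False)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def final_layer(self) -> LayerState:
        return self.layers[-1]

    def required_feature_names(self) -> list[str]:
        """Original feature names the model needs at prediction time."""
        idx = set(self.reinject_cols.tolist())
        for lc in self.layers[0].classifiers:
            idx.update(lc.feature_set.indices.tolist())
        return [self.feature_names[i] for i in sorted(idx)]

    def forward(self, Xn: np.ndarray) -> np.ndarray:
        """Propagate a normalized full-width matrix to the final layer's input."""
        reinjected = Xn[:, self.reinject_cols] if self.reinject_cols.size else None
        X_layer = Xn
        for layer in self.layers[:-1]:
            X_layer = augment_features(layer, X_layer, reinjected, self.config.score_mode)
        return X_layer


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _combine_matrices(
    X: FeatureMatrix, X2: FeatureMatrix | None
) -> tuple[np.ndarray, list[str], int]:
    if X2 is None:
        return X.values, list(X.feature_names), X.n_features
    if list(X2.sample_ids) != list(X.sample_ids):
        raise ValueError("secondary omics matrix must be paired: same sample IDs in order")
    taken = set(X.feature_names)
    names2 = [n if n not in taken else f"omics2|{n}" for n in X2.feature_names]
    return (
        np.hstack([X.values, X2.values]),
        list(X.feature_names) + names2,
        X.n_features,
    )


def fit_cascade(
    X: FeatureMatrix,
    y: LabelVector,
    config: RunConfig | None = None,
    X2: FeatureMatrix | None = None,
    gene_sets: list[tuple[str, list[str]]] | None = None,
) -> CascadeModel:
    """Fit the full deep cascade on one (or a fused pair of) feature matrices.

    With a secondary matrix ``X2``, fusion follows ``config.fusion``:
    ``concatenate`` scans and cascades over the joined matrix, while
    ``secondary_reinject`` builds layer-1 classifiers on the primary matrix
    only and feeds scanned secondary columns to every deeper layer as
    additional re-injected features.
    """
    config = config or RunConfig()
    X, y = align(X, y)
    if X2 is not None:
        missing = [s for s in X.sample_ids if s not in set(X2.sample_ids)]
        if missing:
            raise ValueError(f"secondary matrix is missing samples: {missing[:5]}")
        X2 = X2.subset_samples(X.sample_ids)

    values, names, n_primary = _combine_matrices(X, X2)
    Xn, stats = zscore_fit_apply(values)
    yarr = y.labels

    scan_width = n_primary if (X2 is not None and config.fusion == "secondary_reinject") else len(names)
    scan_ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(0, 0))
    if config.scan_strategy == "random":
        plan = random_scan(
            scan_width, config.n_feature_sets, config.set_size_min, config.set_size_max, scan_ss
        )
        plan.seed = config.seed
    elif config.scan_strategy == "sliding_window":
        plan = sliding_window_scan(scan_width, config.n_feature_sets, config.window_size)
    else:
        if gene_sets is None:
            raise ValueError("scan_strategy 'gene_sets' requires gene_sets")
        plan = gene_set_scan(names[:scan_width], gene_sets, config.min_overlap)

    reinject_cols = plan.scanned_columns() if config.reinject else np.empty(0, dtype=np.int64)
    if X2 is not None and config.fusion == "secondary_reinject" and config.reinject:
        plan2 = random_scan(
            len(names) - n_primary,
            config.n_feature_sets,
            min(config.set_size_min, len(names) - n_primary),
            min(config.set_size_max, len(names) - n_primary),
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0, 1)),
        )
        reinject_cols = np.concatenate([reinject_cols, n_primary + plan2.scanned_columns()])
    reinjected = Xn[:, reinject_cols] if reinject_cols.size else None

    layers: list[LayerState] = []
    layer_log: list[dict] = []
    best_val = -np.inf
    best_idx = 0
    bad = 0
    stop_reason = "max_layers"
    X_layer = Xn
    sets = plan.feature_sets
    for t in range(1, config.max_layers + 1):
        t0 = time.perf_counter()
        layer = train_layer(X_layer, yarr, sets, config, _child_rng(config.seed, 1, t))
        layer.layer_index = t
        layers.append(layer)
        layer_log.append(
            {
                "layer": t,
                "trained": layer.n_trained,
                "pruned": layer.n_pruned,
                "survivors": len(layer.classifiers),
                "val_mcc": layer.val_mcc,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        logger.info(
            "layer %d: trained %d, pruned %d, survivors %d, val MCC %.4f",
            t, layer.n_trained, layer.n_pruned, len(layer.classifiers), layer.val_mcc,
        )
        if layer.val_mcc > best_val:
            best_val = layer.val_mcc
            best_idx = t
            bad = 0
        else:
            bad += 1
            if bad > config.patience:
                stop_reason = "no_improvement"
                break
        if t == config.max_layers:
            break
        X_layer = augment_features(layer, X_layer, reinjected, config.score_mode)
        sets = _deep_layer_sets(X_layer.shape[1], config, _child_rng(config.seed, 2, t))

    retained = layers[:best_idx]
    logger.info(
        "cascade stopped (%s): %d layers retained of %d trained, best val MCC %.4f",
        stop_reason, len(retained), len(layers), best_val,
    )
    return CascadeModel(
        layers=retained,
        scan_plan=plan,
        config=config,
        stop_reason=stop_reason,
        norm_stats=stats,
        feature_names=names,
        n_primary_features=n_primary,
        reinject_cols=reinject_cols,
        positive_class_name=y.positive_class_name,
        layer_log=layer_log,
    )
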