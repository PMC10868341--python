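"""Experimental harness: repeated stratified cross-validation, independent
validation and paired ablation runs.

The harness evaluates any *fitter* — a callable
``fitter(X_train, y_train, config, seed) -> predictor`` where
``predictor(X_test) -> (scores, labels)`` — so the cascade, a single
all-feature nearest-centroid baseline, or any scikit-learn comparator can be
run on identical folds and compared fold-by-fold. Folds are stratified (class
proportions preserved per fold) and every fit gets a seed derived from the
harness root seed, so whole reports reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeModel, fit_cascade, zscore_apply, zscore_fit
from .centroid import fit_centroid, predict_centroid, score_centroid
from .config import RunConfig
from .containers import FeatureMatrix, LabelVector
from .metrics import accuracy, auc, confusion, f1, mcc
from .predict import predict
from .scanning import FeatureSet

_METRIC_COLS = ["mcc", "auc", "accuracy", "f1"]


@dataclass
class MetricsReport:
    """Fold-level metric records plus their aggregate means and SDs."""

    records: pd.DataFrame
    n_repeats: int
    n_folds: int
    seed: int
    aggregate: dict = field(init=False)

    def __post_init__(self) -> None:
        agg = {}
        for m in _METRIC_COLS:
            agg[f"mean_{m}"] = float(self.records[m].mean())
            agg[f"sd_{m}"] = float(self.records[m].std(ddof=1)) if len(self.records) > 1 else 0.0
        self.aggregate = agg

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "aggregate": self.aggregate,
            "folds": self.records.to_dict(orient="records"),
        }


def _derived_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=root, spawn_key=key).generate_state(1)[0] % (2**31))


def cascade_fitter(X: FeatureMatrix, y: LabelVector, config: RunConfig, seed: int):
    """Fit the deep cascade; returns a predictor yielding (vote fraction, labels)."""
    model = fit_cascade(X, y, config.replace(seed=seed))

    def _predict(X_test: FeatureMatrix):
        res = predict(model, X_test)
        return res.probability_positive, res.label

    return _predict


def ncc_fitter(X: FeatureMatrix, y: LabelVector, config: RunConfig, seed: int):
    """Baseline: a single nearest-centroid classifier over all features (z-scored)."""
    stats = zscore_fit(X.values)
    Xn = zscore_apply(stats, X.values)
    fs = FeatureSet(0, np.arange(X.n_features), "all")
    model = fit_centroid(Xn, y.labels, fs, distance=config.distance)

    def _predict(X_test: FeatureMatrix):
        pos = {n: i for i, n in enumerate(X_test.feature_names)}
        idx = [pos[n] for n in X.feature_names]
        Zt = zscore_apply(stats, X_test.values[:, idx])
        return score_centroid(model, Zt), predict_centroid(model, Zt)

    return _predict


def _evaluate_fold(scores, labels, y_true) -> dict:
    c = confusion(y_true, labels)
    return {
        "mcc": mcc(c),
        "auc": auc(y_true, np.asarray(scores, dtype=np.float64)),
        "accuracy": accuracy(c),
        "f1": f1(c),
        "n_test": c.n,
    }


def repeated_cv(
    X: FeatureMatrix,
    y: LabelVector,
    config: RunConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    fitter=cascade_fitter,
) -> MetricsReport:
    """Repeated stratified k-fold cross-validation with per-fold refits.

    Every repeat reshuffles the stratified folds; the model is refit from
    scratch on each training split and scored on the held-out fold.
    """
    config = config or RunConfig()
    yarr = y.labels
    n_pos = int(yarr.sum())
    n_neg = len(yarr) - n_pos
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} samples < k={k}; use a smaller k"
        )
    rows = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=_derived_seed(seed, r))
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(yarr)), yarr)):
            ids_tr = [X.sample_ids[i] for i in tr]
            ids_te = [X.sample_ids[i] for i in te]
            predictor = fitter(
                X.subset_samples(ids_tr), y.subset(ids_tr), config, _derived_seed(seed, r, fold)
            )
            scores, labels = predictor(X.subset_samples(ids_te))
            rows.append({"repeat": r, "fold": fold, **_evaluate_fold(scores, labels, yarr[te])})
    return MetricsReport(pd.DataFrame(rows), n_repeats=repeats, n_folds=k, seed=seed)


def independent_validation(
    X_train: FeatureMatrix,
    y_train: LabelVector,
    X_test: FeatureMatrix,
    y_test: LabelVector,
    config: RunConfig | None = None,
    n_runs: int = 3,
    seed: int = 0,
    fitter=cascade_fitter,
) -> MetricsReport:
    """Train on one cohort, evaluate on a disjoint cohort, averaged over refits.

    Because fits are stochastic, the model is refit ``n_runs`` times with
    derived seeds and the test metrics are averaged. Train and test sample ID
    sets must be disjoint.
    """
    config = config or RunConfig()
    overlap = sorted(set(X_train.sample_ids) & set(X_test.sample_ids))
    if overlap:
        raise ValueError(f"train and test cohorts share sample IDs: {overlap[:10]}")
    rows = []
    for r in range(n_runs):
        predictor = fitter(X_train, y_train, config, _derived_seed(seed, r))
        scores, labels = predictor(X_test)
        rows.append({"repeat": r, "fold": 0, **_evaluate_fold(scores, labels, y_test.labels)})
    return MetricsReport(pd.DataFrame(rows), n_repeats=n_runs, n_folds=1, seed=seed)


def run_ablation(
    X: FeatureMatrix,
    y: LabelVector,
    variants: dict[str, RunConfig],
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    fitter=cascade_fitter,
) -> dict[str, MetricsReport]:
    """Run several configurations on identical folds for paired comparison.

    All variants share the harness seed, hence identical fold assignments and
    aligned (repeat, fold) records.
    """
    return {
        name: repeated_cv(X, y, cfg, k=k, repeats=repeats, seed=seed, fitter=fitter)
        for name, cfg in variants.items()
    }
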