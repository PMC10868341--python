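"""File I/O: delimited matrices, label tables, GMT gene sets, model artifacts.

Matrices are dense TSV/CSV with one header row of names and one leading ID
column; the orientation (samples in rows vs features in rows) is always
declared by the caller, never guessed — public omics matrices ship both ways.
Missing values are rejected by default; optional per-feature mean imputation
can be requested explicitly.

Fitted cascades are persisted as a versioned JSON container of plain arrays
plus the run configuration — no opaque pickles — so artifacts remain
inspectable and loadable across versions, and a round-tripped model predicts
bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeModel, LayerClassifier, LayerState, NormStats
from .centroid import CentroidModel, NearestCentroidBase
from .config import RunConfig
from .containers import FeatureMatrix, LabelVector, _find_duplicates
from .scanning import FeatureSet, ScanPlan

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
    impute_mean: bool = False,
) -> FeatureMatrix:
    """Read a dense numeric matrix with an ID column and a name header row.

    ``orientation`` declares the file layout: ``samples_in_rows`` (default) or
    ``features_in_rows`` (the matrix is transposed after reading). Non-numeric
    cells and duplicate IDs are hard errors with coordinates; missing values
    are errors unless ``impute_mean`` requests per-feature mean imputation.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError("orientation must be 'samples_in_rows' or 'features_in_rows'")
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), index_col=0, dtype=str)
    dup_rows = _find_duplicates([str(i) for i in df.index])
    dup_cols = _find_duplicates([str(c) for c in df.columns])
    if dup_rows or dup_cols:
        raise ValueError(f"duplicate IDs in {path.name}: {dup_rows + dup_cols}")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna()
        bad = converted.isna() & ~raw_missing
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[i]!r} at row {df.index[i]!r}, "
                f"column {col!r} in {path.name}"
            )
        values[:, j] = converted.to_numpy(dtype=np.float64)
    if orientation == "features_in_rows":
        values = values.T
        sample_ids = [str(c) for c in df.columns]
        feature_names = [str(i) for i in df.index]
    else:
        sample_ids = [str(i) for i in df.index]
        feature_names = [str(c) for c in df.columns]
    nan_mask = np.isnan(values)
    if nan_mask.any():
        if not impute_mean:
            i, j = np.argwhere(nan_mask)[0]
            raise ValueError(
                f"missing value at sample {sample_ids[i]!r}, feature "
                f"{feature_names[j]!r} in {path.name}; pass impute_mean=True to impute"
            )
        col_means = np.nanmean(values, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        values[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        logger.info("imputed %d missing values with per-feature means", int(nan_mask.sum()))
    return FeatureMatrix(sample_ids, feature_names, values)


def write_matrix(matrix: FeatureMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path, delimiter), index_label="id")


def read_labels(path: str | Path, positive: str, delimiter: str | None = None) -> LabelVector:
    """Read a two-column (sample ID, class string) table; map ``positive`` to 1."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path.name} must have two columns: sample ID and class")
    ids = [str(v) for v in df.iloc[:, 0]]
    classes = [str(v) for v in df.iloc[:, 1]]
    dup = _find_duplicates(ids)
    if dup:
        raise ValueError(f"duplicate sample IDs in {path.name}: {dup}")
    distinct = sorted(set(classes))
    if len(distinct) > 2:
        raise ValueError(f"more than two classes in {path.name}: {distinct}")
    if positive not in distinct:
        raise ValueError(f"positive class {positive!r} not present; classes are {distinct}")
    labels = np.array([1 if c == positive else 0 for c in classes], dtype=np.int64)
    return LabelVector(ids, labels, positive_class_name=positive)


def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a GMT gene-set file: name, description, then tab-separated members.

    Returns (name, members) pairs in file order; members are deduplicated
    within a set preserving first occurrence.
    """
    path = Path(path)
    sets: list[tuple[str, list[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
        members = list(dict.fromkeys(m for m in fields[2:] if m))
        sets.append((fields[0], members))
    return sets


# ---------------------------------------------------------------------------
# model persistence


def save_model(model: CascadeModel, path: str | Path) -> None:
    """Serialize a fitted cascade to versioned JSON (plain arrays + config)."""
    for layer in model.layers:
        for lc in layer.classifiers:
            if not isinstance(lc.base, NearestCentroidBase):
                raise ValueError(
                    "only nearest-centroid cascades are serializable in model format v1"
                )
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "stop_reason": model.stop_reason,
        "positive_class_name": model.positive_class_name,
        "feature_names": model.feature_names,
        "n_primary_features": model.n_primary_features,
        "reinject_cols": model.reinject_cols.tolist(),
        "norm_mean": model.norm_stats.mean.tolist(),
        "norm_sd": model.norm_stats.sd.tolist(),
        "scan_plan": {
            "strategy": model.scan_plan.strategy,
            "seed": model.scan_plan.seed,
            "n_features_total": model.scan_plan.n_features_total,
            "params": model.scan_plan.params,
        },
        "layers": [
            {
                "layer_index": layer.layer_index,
                "val_mcc": layer.val_mcc,
                "n_trained": layer.n_trained,
                "n_pruned": layer.n_pruned,
                "classifiers": [
                    {
                        "set_id": lc.feature_set.set_id,
                        "source": lc.feature_set.source,
                        "indices": lc.feature_set.indices.tolist(),
                        "centroid_pos": lc.base.model.centroid_pos.tolist(),
                        "centroid_neg": lc.base.model.centroid_neg.tolist(),
                        "distance": lc.base.model.distance,
                        "val_mcc": lc.val_mcc,
                    }
                    for lc in layer.classifiers
                ],
            }
            for layer in model.layers
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> CascadeModel:
    """Load a cascade saved by :func:`save_model`; version mismatch is a hard error."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is corrupt or truncated: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    config = RunConfig.from_dict(doc["config"])
    layers = []
    for ld in doc["layers"]:
        classifiers = []
        for cd in ld["classifiers"]:
            fs = FeatureSet(cd["set_id"], np.asarray(cd["indices"], dtype=np.int64), cd["source"])
            base = NearestCentroidBase(fs, cd["distance"])
            base.model = CentroidModel(
                feature_set=fs,
                centroid_pos=np.asarray(cd["centroid_pos"], dtype=np.float64),
                centroid_neg=np.asarray(cd["centroid_neg"], dtype=np.float64),
                distance=cd["distance"],
                val_mcc=cd["val_mcc"],
            )
            classifiers.append(LayerClassifier(base=base, val_mcc=cd["val_mcc"], split=None))
        layers.append(
            LayerState(
                layer_index=ld["layer_index"],
                classifiers=classifiers,
                val_mcc=ld["val_mcc"],
                n_trained=ld["n_trained"],
                n_pruned=ld["n_pruned"],
            )
        )
    sp = doc["scan_plan"]
    plan = ScanPlan(
        feature_sets=[lc.feature_set for lc in layers[0].classifiers],
        n_features_total=sp["n_features_total"],
        strategy=sp["strategy"],
        seed=sp["seed"],
        params=sp["params"],
    )
    return CascadeModel(
        layers=layers,
        scan_plan=plan,
        config=config,
        stop_reason=doc["stop_reason"],
        norm_stats=NormStats(
            mean=np.asarray(doc["norm_mean"], dtype=np.float64),
            sd=np.asarray(doc["norm_sd"], dtype=np.float64),
        ),
        feature_names=list(doc["feature_names"]),
        n_primary_features=doc["n_primary_features"],
        reinject_cols=np.asarray(doc["reinject_cols"], dtype=np.int64),
        positive_class_name=doc["positive_class_name"],
    )
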