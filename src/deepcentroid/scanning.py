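"""Feature scanning: turning one wide matrix into many feature sets.

Omics features arrive in an order (gene symbol, probe ID, genomic position)
that usually carries no biological meaning, so contiguous windows — the
convolution-like trick of Deep Forest — extract no meaningful "local"
structure. The default strategy therefore draws many *random* feature sets of
varying sizes; each set feeds one base classifier. A sliding-window strategy
is kept as the ablation comparator, and curated gene sets (e.g. MSigDB GO/KEGG
collections read from GMT files) can supply prior-knowledge sets instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_PLAN_FORMAT_VERSION = 1


@dataclass
class FeatureSet:
    """An ordered set of distinct column indices; one base classifier per set."""

    set_id: int
    indices: np.ndarray
    source: str = "random"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1 or self.indices.size < 1:
            raise ValueError("indices must be a non-empty 1-D array")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError(f"feature set {self.set_id} has repeated indices")

    @property
    def size(self) -> int:
        return int(self.indices.size)


@dataclass
class ScanPlan:
    """A reproducible collection of feature sets over one matrix width."""

    feature_sets: list[FeatureSet]
    n_features_total: int
    strategy: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fs in self.feature_sets:
            if fs.indices.max() >= self.n_features_total:
                raise ValueError(
                    f"set {fs.set_id} references index {fs.indices.max()} "
                    f">= n_features_total {self.n_features_total}"
                )

    def __len__(self) -> int:
        return len(self.feature_sets)

    def scanned_columns(self) -> np.ndarray:
        """Sorted union of all column indices touched by the plan."""
        if not self.feature_sets:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate([fs.indices for fs in self.feature_sets]))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": _PLAN_FORMAT_VERSION,
            "strategy": self.strategy,
            "seed": self.seed,
            "n_features_total": self.n_features_total,
            "params": self.params,
            "feature_sets": [
                {"set_id": fs.set_id, "source": fs.source, "indices": fs.indices.tolist()}
                for fs in self.feature_sets
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanPlan":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != _PLAN_FORMAT_VERSION:
            raise ValueError(
                f"unsupported scan plan format version {doc.get('format_version')!r}"
            )
        sets = [
            FeatureSet(d["set_id"], np.asarray(d["indices"], dtype=np.int64), d["source"])
            for d in doc["feature_sets"]
        ]
        return cls(sets, doc["n_features_total"], doc["strategy"], doc["seed"], doc["params"])


def random_scan(
    n_features: int,
    n_sets: int = 500,
    size_min: int = 10,
    size_max: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> ScanPlan:
    """Draw ``n_sets`` random feature sets with sizes uniform on [size_min, size_max].

    Set members are sampled without replacement within a set; different sets
    may overlap freely.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not (1 <= size_min <= size_max):
        raise ValueError("need 1 <= size_min <= size_max")
    if size_max > n_features:
        raise ValueError(
            f"size_max {size_max} exceeds n_features {n_features}; "
            "lower set_size_max or supply more features"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(size_min, size_max + 1))
        idx = rng.choice(n_features, size=size, replace=False)
        sets.append(FeatureSet(k, idx, source="random"))
    seed_repr = seed if isinstance(seed, int) else -1
    return ScanPlan(
        sets,
        n_features,
        "random",
        seed=seed_repr,
        params={"size_min": size_min, "size_max": size_max},
    )


def sliding_window_scan(n_features: int, n_sets: int = 500, window: int = 100) -> ScanPlan:
    """Contiguous windows of fixed width stepped across the feature axis.

    The step is ``max(1, floor(n_features / n_sets))``; windows that would run
    past the end are clamped so the final set ends exactly at ``n_features``.
    Exactly ``n_sets`` sets are produced.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if window > n_features:
        raise ValueError(f"window {window} exceeds n_features {n_features}")
    step = max(1, n_features // n_sets)
    sets = []
    for k in range(n_sets):
        start = min(k * step, n_features - window)
        sets.append(FeatureSet(k, np.arange(start, start + window), source="window"))
    return ScanPlan(sets, n_features, "sliding_window", seed=0, params={"window": window, "step": step})


def gene_set_scan(
    feature_names: list[str],
    gene_sets: list[tuple[str, list[str]]],
    min_overlap: int = 10,
) -> ScanPlan:
    """Turn named gene sets into feature sets by intersection with the matrix.

    Sets whose overlap with the available feature names falls below
    ``min_overlap`` are dropped (logged).
    """
    if not feature_names:
        raise ValueError("feature_names must be non-empty")
    pos = {name: i for i, name in enumerate(feature_names)}
    sets: list[FeatureSet] = []
    n_dropped = 0
    for name, members in gene_sets:
        idx = [pos[m] for m in members if m in pos]
        if len(idx) < min_overlap:
            n_dropped += 1
            continue
        sets.append(
            FeatureSet(len(sets), np.asarray(idx, dtype=np.int64), source=f"gene_set:{name}")
        )
    if n_dropped:
        logger.info("gene_set_scan: dropped %d sets with overlap < %d", n_dropped, min_overlap)
    if not sets:
        raise ValueError(
            "no gene set overlaps the matrix features at the requested min_overlap; "
            "consider random scanning instead"
        )
    return ScanPlan(sets, len(feature_names), "gene_sets", seed=0, params={"min_overlap": min_overlap})
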