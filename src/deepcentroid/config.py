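"""Run configuration.

Defaults reproduce the published method settings: 500 feature sets with sizes
drawn uniformly on [10, 200] for random scanning, sliding window of 100 with
step = floor(n_features / n_sets), sampling coefficient 0.65 for the balanced
with-replacement resample, and out-of-bag MCC pruning at threshold 0.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

SCAN_STRATEGIES = ("random", "sliding_window", "gene_sets")
DISTANCES = ("euclidean", "correlation")
FUSION_MODES = ("concatenate", "secondary_reinject")
COEFFICIENT_CLASSES = ("minority", "positive")


@dataclass
class RunConfig:
    """All tunable parameters of a cascade fit.

    Attributes
    ----------
    scan_strategy
        How feature sets are formed: ``random`` (default), ``sliding_window``
        (contiguous windows, the ablation comparator) or ``gene_sets``
        (prior-knowledge sets from a GMT file).
    n_feature_sets
        Number of feature sets, hence base classifiers per layer (default 500).
    set_size_min, set_size_max
        Bounds of the uniform set-size law for random scanning (defaults 10, 200).
    window_size
        Sliding-window width (default 100, the median random-set size).
    sampling_coefficient
        Fraction of the with-replacement training draw allocated to the
        minority class (default 0.65), pushing each resample toward balance.
    coefficient_class
        Which class the coefficient anchors to: ``minority`` (default) or
        ``positive``.
    prune_threshold
        Base classifiers with out-of-bag MCC <= this value are removed
        (default 0.0).
    max_layers
        Hard cap on cascade depth (default 20).
    patience
        Number of consecutive non-improving layers tolerated before stopping
        (default 0: stop at first non-improvement).
    base_classifier
        Identifier of the base learner (default ``nearest_centroid``).
    distance
        Distance metric for the centroid classifier (default ``euclidean``).
    score_mode
        ``signed``: one signed distance score per classifier feeds the next
        layer; ``two_distance``: both raw centroid distances are forwarded.
    reinject
        Whether scanned original features are re-injected into every cascade
        layer alongside classifier scores (default True).
    fusion
        Multi-omics mode: ``concatenate`` (matrices joined as layer-1 input)
        or ``secondary_reinject`` (secondary omics enters only as re-injected
        scan columns at deeper layers).
    min_overlap
        Minimum intersection with available features for a gene set to be kept.
    seed
        Root seed; all randomness derives from it.
    """

    scan_strategy: str = "random"
    n_feature_sets: int = 500
    set_size_min: int = 10
    set_size_max: int = 200
    window_size: int = 100
    sampling_coefficient: float = 0.65
    coefficient_class: str = "minority"
    prune_threshold: float = 0.0
    max_layers: int = 20
    patience: int = 0
    base_classifier: str = "nearest_centroid"
    distance: str = "euclidean"
    score_mode: str = "signed"
    reinject: bool = True
    fusion: str = "concatenate"
    min_overlap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scan_strategy not in SCAN_STRATEGIES:
            raise ValueError(f"scan_strategy must be one of {SCAN_STRATEGIES}")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}")
        if self.coefficient_class not in COEFFICIENT_CLASSES:
            raise ValueError(f"coefficient_class must be one of {COEFFICIENT_CLASSES}")
        if self.score_mode not in ("signed", "two_distance"):
            raise ValueError("score_mode must be 'signed' or 'two_distance'")
        if self.n_feature_sets < 1:
            raise ValueError("n_feature_sets must be >= 1")
        if not (1 <= self.set_size_min <= self.set_size_max):
            raise ValueError("need 1 <= set_size_min <= set_size_max")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0.0 < self.sampling_coefficient < 1.0):
            raise ValueError("sampling_coefficient must be in (0, 1)")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def replace(self, **kw) -> "RunConfig":
        d = self.to_dict()
        d.update(kw)
        return RunConfig.from_dict(d)
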