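"""Synthetic omics-like data with known ground truth.

The generator emulates the statistical shape of the classification problems
the cascade targets — high-dimensional, low-sample binary cohorts with class
imbalance and cross-cohort batch shift — without any real-data download:

* features are Gaussian noise except for a planted set of *informative*
  features whose class-conditional means differ by ``effect_size`` (in SD
  units), optionally equicorrelated through a shared latent factor;
* class imbalance is set by a positive:negative ratio;
* an *independent cohort* is drawn from the same law with a location shift
  (random sign) added to a random half of the features, mimicking the
  source-to-source inconsistencies of public omics cohorts;
* informative feature positions are scattered by random permutation (default),
  so contiguous-window scanning gains nothing from feature order — mirroring
  real matrices where adjacent columns are biologically unrelated;
* a paired secondary omics matrix (for fusion experiments) can carry its own
  informative set, a chosen fraction of which shares the class signal.

Everything is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix, LabelVector


@dataclass
class SimScenario:
    """Parameters of one synthetic study.

    Defaults describe the standard test condition used throughout the package:
    200 samples, 2000 features of which 50 are informative, class-mean shift
    of 1.0 SD, 1:3 positive:negative imbalance.
    """

    n_samples: int = 200
    n_features: int = 2000
    n_informative: int = 50
    effect_size: float = 1.0
    imbalance: tuple[int, int] = (1, 3)  # positive : negative
    batch_shift: float = 0.5
    noise_sd: float = 1.0
    block_correlation: float = 0.3
    shuffle_features: bool = True
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_informative <= self.n_features):
            raise ValueError("need 0 < n_informative <= n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ValueError("block_correlation must be in [0, 1)")
        pos, neg = self.imbalance
        if pos <= 0 or neg <= 0:
            raise ValueError("imbalance ratio parts must be positive")
        if self.n_positive == 0 or self.n_positive == self.n_samples:
            raise ValueError("imbalance leaves a class empty at this n_samples")

    @property
    def n_positive(self) -> int:
        pos, neg = self.imbalance
        return int(round(self.n_samples * pos / (pos + neg)))


@dataclass
class SimOutput:
    """One simulated study: training cohort, batch-shifted independent cohort, truth."""

    train_X: FeatureMatrix
    train_y: LabelVector
    independent_X: FeatureMatrix
    independent_y: LabelVector
    truth: list[str]
    secondary_X: FeatureMatrix | None = None
    secondary_truth: list[str] = field(default_factory=list)


def _draw_noise(rng: np.random.Generator, shape, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        # t(4) scaled to unit variance, then to sd
        return rng.standard_t(4, size=shape) / np.sqrt(2.0) * sd
    return rng.normal(0.0, sd, size=shape)


def _cohort(
    rng: np.random.Generator, sc: SimScenario, n: int, informative_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One cohort: labels then the matrix with planted class signal."""
    n_pos = int(round(n * sc.imbalance[0] / sum(sc.imbalance)))
    y = np.zeros(n, dtype=np.int64)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    X = _draw_noise(rng, (n, sc.n_features), sc.noise_sd, sc.heavy_tails)
    rho = sc.block_correlation
    if rho > 0:
        z = rng.normal(0.0, 1.0, size=n)
        eps = _draw_noise(rng, (n, informative_cols.size), 1.0, sc.heavy_tails)
        X[:, informative_cols] = sc.noise_sd * (
            np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * eps
        )
    X[np.ix_(y == 1, informative_cols)] += sc.effect_size * sc.noise_sd
    return X, y


def simulate(scenario: SimScenario | None = None) -> SimOutput:
    """Generate a training cohort and a batch-shifted independent cohort."""
    sc = scenario or SimScenario()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=sc.seed, spawn_key=(10,)))
    if sc.shuffle_features:
        informative_cols = np.sort(rng.choice(sc.n_features, size=sc.n_informative, replace=False))
    else:
        informative_cols = np.arange(sc.n_informative)
    feature_names = [f"g{j + 1:05d}" for j in range(sc.n_features)]
    truth = [feature_names[j] for j in informative_cols]

    X_tr, y_tr = _cohort(rng, sc, sc.n_samples, informative_cols)
    X_te, y_te = _cohort(rng, sc, sc.n_samples, informative_cols)
    if sc.batch_shift != 0.0:
        shifted = rng.choice(sc.n_features, size=sc.n_features // 2, replace=False)
        signs = rng.choice([-1.0, 1.0], size=shifted.size)
        X_te[:, shifted] += sc.batch_shift * sc.noise_sd * signs

    ids_tr = [f"train_s{i + 1:04d}" for i in range(sc.n_samples)]
    ids_te = [f"indep_s{i + 1:04d}" for i in range(sc.n_samples)]
    return SimOutput(
        train_X=FeatureMatrix(ids_tr, feature_names, X_tr),
        train_y=LabelVector(ids_tr, y_tr, "case"),
        independent_X=FeatureMatrix(ids_te, feature_names, X_te),
        independent_y=LabelVector(ids_te, y_te, "case"),
        truth=truth,
    )


def simulate_multiomics(
    scenario: SimScenario | None = None,
    n_features_secondary: int = 1000,
    shared_signal_fraction: float = 0.5,
) -> SimOutput:
    """Add a paired secondary omics matrix to a simulated study.

    The secondary matrix has its own planted informative set of the same size
    as the primary one; ``shared_signal_fraction`` of those features carry the
    class signal (mean shift by the scenario effect size), the rest are driven
    by a latent factor unrelated to class.
    """
    if not (0.0 <= shared_signal_fraction <= 1.0):
        raise ValueError("shared_signal_fraction must be in [0, 1]")
    sc = scenario or SimScenario()
    out = simulate(sc)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=sc.seed, spawn_key=(11,)))
    n = sc.n_samples
    n_inf = min(sc.n_informative, n_features_secondary)
    X2 = _draw_noise(rng, (n, n_features_secondary), sc.noise_sd, sc.heavy_tails)
    cols = np.sort(rng.choice(n_features_secondary, size=n_inf, replace=False))
    n_shared = int(round(shared_signal_fraction * n_inf))
    shared = cols[:n_shared]
    y = out.train_y.labels
    X2[np.ix_(y == 1, shared)] += sc.effect_size * sc.noise_sd
    latent = rng.normal(0.0, 1.0, size=n)
    X2[:, cols[n_shared:]] += sc.noise_sd * 0.5 * latent[:, None]
    names2 = [f"m{j + 1:05d}" for j in range(n_features_secondary)]
    out.secondary_X = FeatureMatrix(list(out.train_X.sample_ids), names2, X2)
    out.secondary_truth = [names2[j] for j in shared]
    return out
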