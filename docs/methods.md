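# Methods

This note documents the model implemented by `deepcentroid`, the conventions
and numerical choices it commits to, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Model and assumptions

The classifier is a cascade ensemble for binary labels on a dense
samples × features matrix. Its base learner is the plain (unshrunken)
nearest-centroid classifier, chosen for stability on independent cohorts;
the cascade adds fitting capacity the base learner lacks. The method assumes:

* features are meaningfully comparable after per-feature standardization
  (z-score with training-set statistics);
* class signal is carried by an unknown subset of features, not by feature
  order — random subsets are as good a grouping as any contiguous window;
* a single signed distance score per base classifier is a sufficient summary
  to pass to the next layer (a two-distance mode is available for
  sensitivity analysis, `score_mode="two_distance"`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_feature_sets` | 500 | base classifiers per layer |
| `set_size_min/max` | 10 / 200 | uniform integer law for random set sizes |
| `window_size` | 100 | sliding-window width (ablation comparator; the median random size) |
| `sampling_coefficient` | 0.65 | fraction of the n with-replacement draws taken from the minority class |
| `prune_threshold` | 0.0 | survivors need OOB MCC strictly above this |
| `max_layers` | 20 | hard depth cap |
| `patience` | 0 | non-improving layers tolerated before stopping |
| `distance` | euclidean | centroid distance; `correlation` (1 − Pearson r) optional |
| `fusion` | concatenate | multi-omics mode; `secondary_reinject` feeds the second matrix to deeper layers only |
| `min_overlap` | 10 | minimum intersection for a gene set to be kept (matches the random-scan lower bound) |

The ensemble-size and resampling defaults (500 sets, sizes 10–200, window
100 with step = ⌊n_features / n_sets⌋, coefficient 0.65, threshold 0) are the
method's published operating point and are asserted by tests.

Interpretation of the sampling coefficient: `round(0.65·n)` of the n
with-replacement draws come from the *minority* class (ties broken toward the
positive class), pushing each bootstrap toward balance;
`coefficient_class="positive"` anchors it to the positive class instead.

## Layer evaluation and stopping

Each base classifier is validated on its own out-of-bag samples. The
layer-level score used by the stopping rule is an out-of-bag ensemble
estimate: every training sample is majority-voted only by the surviving
classifiers for which it is out-of-bag, and the MCC of those votes is the
layer's validation MCC. Training continues while this strictly improves
(ties count as non-improvement); with `patience > 0` that many consecutive
non-improving layers are tolerated. The retained model is the best prefix of
layers, so at `patience = 0` retained layer MCCs are strictly increasing.

Deep layers receive `[survivor score columns | re-injected scan columns]`.
Re-injected columns are the deduplicated union of all columns touched by the
stage-1 scan plan (identical information to per-set copies at linear memory).
Deep-layer feature sets are fresh random subsets over that augmented input,
drawn with the same size law clamped to the input width; the stage-1 plan
itself is not re-scanned at depth.

## Numerical conventions

* z-score uses the population denominator (ddof = 0); constant training
  columns map to 0, for training and new data alike.
* MCC returns 0 whenever a denominator factor is 0 (this also means a
  classifier whose OOB set lacks one class scores 0 and is pruned).
* AUC is the Mann–Whitney rank statistic with ties counted ½.
* Score tie (exactly 0) predicts negative; vote tie (fraction exactly 0.5)
  predicts negative. Both deterministic and conservative for case/control
  screening.
* Sliding windows clamp at the right edge (the last windows shift left so the
  final one ends exactly at `n_features`), preserving the set count and
  contiguity.
* All randomness derives from the root seed through `numpy.random.SeedSequence`
  spawn keys — `(0, ·)` for scanning, `(1, layer)` for layer training,
  `(2, layer)` for deep-layer set drawing — so fits, predictions and CV
  reports are bit-reproducible.
* Bootstrap draws are redrawn (bounded retries) in the rare event that the
  out-of-bag set is empty or a class is missing from the draw.

## Feature importance

The ranking targets the genes inside high-performing base classifiers. A
set-level credit alone (e.g. the mean OOB MCC of the surviving classifiers
containing a feature) is uninformative at realistic set sizes: with 10–200
features per set, one feature moves its set's MCC far less than between-set
noise, and the ranking degenerates. The implemented importance therefore
couples the classifier's quality with the feature's own contribution inside
it:

    importance(j) = mean over surviving first-layer classifiers containing j
                    of  val_mcc · |μ₊ⱼ − μ₋ⱼ|

i.e. OOB MCC times the between-class centroid separation on that feature (on
z-scored data). Only first-layer classifiers participate — deeper layers
operate on derived score columns. On the standard synthetic condition this
ranking recovers essentially all planted markers (precision@50 ≈ 1.0),
whereas the set-level mean scores ≈ 0.12. For non-centroid base learners the
separation term is unavailable and the credit falls back to OOB MCC alone.

## Synthetic data

The generator produces the statistical shape of the target problems, not
their biology: Gaussian noise features; a planted informative subset whose
class-conditional means differ by `effect_size` (in SD units), optionally
equicorrelated through a shared latent factor (`block_correlation`, default
0.3 — a mild functional-module-like correlation); configurable
positive:negative imbalance; an independent cohort drawn from the same law
with a random-sign location shift (default 0.5 SD) on a random half of the
features, emulating cross-source batch effects; informative positions
scattered by random permutation so window scanning gains nothing from order.
A paired secondary matrix for fusion experiments carries its own informative
set, a chosen fraction sharing the class signal. A t(4) option
(`heavy_tails`) exists for robustness checks.

The standard study condition used across tests and the acceptance script is
200 samples × 2000 features, 50 informative, effect 1.0 SD, 1:3 imbalance.
Unit tests use a scaled-down version (80 × 300, 20 informative, 60 feature
sets); the acceptance script and the heavier seeded checks in the test suite
average 10 independently seeded studies with 5-fold cross-validation. What passing these tests shows is that the machinery behaves as
specified under its own generative assumptions; it does not certify
performance on real cohorts, where signal is weaker, non-Gaussian, and
confounded in ways the generator does not model (no fragmentomics biology,
no methylation beta-value distributions, no probe-level artifacts).

## Design choices that were genuinely open

* **Set-size law**: uniform integer on [10, 200]; only the range is
  prescribed by the method's operating point.
* **Signed score vs two distances** per classifier fed forward: signed score
  by default (minimal faithful encoding); flag to switch.
* **Scan reuse at depth**: the stage-1 scanned columns are re-injected at
  every layer; deep sets are re-drawn over the augmented input (mirroring
  cascade-forest practice), rather than re-scanning 500 fresh sets of the
  original matrix per layer.
* **Layer stopping statistic**: OOB ensemble vote MCC (no external
  validation file, keeping all samples available for training).
* **Model persistence**: versioned JSON of plain arrays and the config — no
  pickles — so artifacts are inspectable and robust across versions.

## Known limitations

* With a very small minority class, the minority-heavy bootstrap leaves few
  minority samples out of bag; OOB MCC then collapses to 0 for many
  classifiers and pruning turns conservative (see the balanced-class choice
  in the gene-set example). Below roughly 30 minority samples, consider a
  smaller sampling coefficient.
* The probability output is a vote fraction over ~500 voters: granular, not
  calibrated; AUC from it is coarser than from a continuous margin.
* Binary labels only, by design.
* Serialization covers nearest-centroid cascades; wrapped scikit-learn base
  learners are benchmarking aids and are not persisted.
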