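import numpy as np
import pytest

from deepcentroid import (
    FeatureMatrix,
    FeatureSet,
    predict,
    rank_important_features,
)
from deepcentroid.cascade import CascadeModel, LayerClassifier, LayerState, NormStats
from deepcentroid.centroid import CentroidModel, NearestCentroidBase
from deepcentroid.config import RunConfig
from deepcentroid.scanning import ScanPlan


def _manual_model(centroid_pairs, val_mccs=None, n_features=4):
    """Hand-built single-layer cascade with known voting behavior."""
    val_mccs = val_mccs or [0.5] * len(centroid_pairs)
    classifiers = []
    for i, ((cp, cn), vm) in enumerate(zip(centroid_pairs, val_mccs)):
        fs = FeatureSet(i, np.arange(len(cp)), "manual")
        base = NearestCentroidBase(fs)
        base.model = CentroidModel(fs, np.asarray(cp, float), np.asarray(cn, float))
        classifiers.append(LayerClassifier(base=base, val_mcc=vm))
    layer = LayerState(1, classifiers, val_mcc=0.5, n_trained=len(classifiers), n_pruned=0)
    names = [f"f{j}" for j in range(n_features)]
    plan = ScanPlan([c.feature_set for c in classifiers], n_features, "random")
    return CascadeModel(
        layers=[layer],
        scan_plan=plan,
        config=RunConfig(n_feature_sets=len(classifiers)),
        stop_reason="max_layers",
        norm_stats=NormStats(np.zeros(n_features), np.ones(n_features)),
        feature_names=names,
        n_primary_features=n_features,
        reinject_cols=np.empty(0, dtype=np.int64),
    )


def _fm(values, n_features=4):
    values = np.atleast_2d(values)
    return FeatureMatrix(
        [f"s{i}" for i in range(values.shape[0])],
        [f"f{j}" for j in range(n_features)],
        values,
    )


class TestVoting:
    def test_two_of_three_votes_gives_two_thirds(self):
        # sample at origin: two classifiers place the positive centroid nearer, one farther
        model = _manual_model(
            [([0, 0, 0, 0], [5, 5, 5, 5]), ([0, 0, 0, 0], [3, 3, 3, 3]), ([5, 5, 5, 5], [0, 0, 0, 0])]
        )
        res = predict(model, _fm(np.zeros(4)))
        assert res.n_voters == 3
        assert res.probability_positive[0] == pytest.approx(2 / 3)
        assert res.label[0] == 1

    def test_unanimous_negative(self):
        model = _manual_model([([5, 5, 5, 5], [0, 0, 0, 0])] * 3)
        res = predict(model, _fm(np.zeros(4)))
        assert res.probability_positive[0] == 0.0
        assert res.label[0] == 0

    def test_half_split_tie_predicts_negative(self):
        model = _manual_model(
            [([0, 0, 0, 0], [5, 5, 5, 5]), ([5, 5, 5, 5], [0, 0, 0, 0])]
        )
        res = predict(model, _fm(np.zeros(4)))
        assert res.probability_positive[0] == 0.5
        assert res.label[0] == 0

    def test_vote_fraction_times_voters_is_integer(self, fitted_model, small_sim):
        res = predict(fitted_model, small_sim.independent_X)
        counts = res.probability_positive * res.n_voters
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert res.n_voters == len(fitted_model.final_layer.classifiers)

    def test_sample_permutation_permutes_outputs(self, fitted_model, small_sim, rng):
        X = small_sim.independent_X
        perm = rng.permutation(X.n_samples)
        ids = [X.sample_ids[i] for i in perm]
        res = predict(fitted_model, X)
        res_p = predict(fitted_model, X.subset_samples(ids))
        np.testing.assert_array_equal(res.probability_positive[perm], res_p.probability_positive)
        np.testing.assert_array_equal(res.label[perm], res_p.label)

    def test_missing_required_feature_listed(self, fitted_model, small_sim):
        X = small_sim.independent_X
        required = fitted_model.required_feature_names()
        keep = [n for n in X.feature_names if n != required[0]]
        pos = {n: i for i, n in enumerate(X.feature_names)}
        reduced = FeatureMatrix(
            list(X.sample_ids), keep, X.values[:, [pos[n] for n in keep]]
        )
        with pytest.raises(ValueError, match=required[0]):
            predict(fitted_model, reduced)


class TestImportance:
    def test_single_survivor_credit_is_mcc_times_separation(self):
        cp, cn = [1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]
        model = _manual_model([(cp, cn)], val_mccs=[0.4])
        table = rank_important_features(model, top_k=4)
        row = table.set_index("feature_name").loc["f0"]
        assert row["importance"] == pytest.approx(0.4 * 1.0)
        assert row["n_classifiers_containing"] == 1
        assert table.set_index("feature_name").loc["f1", "importance"] == pytest.approx(0.0)

    def test_features_outside_all_survivors_absent(self):
        fs = FeatureSet(0, np.array([0, 1]), "manual")
        base = NearestCentroidBase(fs)
        base.model = CentroidModel(fs, np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        layer = LayerState(1, [LayerClassifier(base=base, val_mcc=0.3)], 0.3, 1, 0)
        model = _manual_model([([0.0] * 4, [1.0] * 4)])
        model.layers = [layer]
        table = rank_important_features(model, top_k=10)
        assert set(table.feature_name) == {"f0", "f1"}

    def test_table_sorted_descending_and_deterministic(self, fitted_model):
        a = rank_important_features(fitted_model, top_k=30)
        b = rank_important_features(fitted_model, top_k=30)
        assert (a.importance.values[:-1] >= a.importance.values[1:]).all()
        assert a.equals(b)

    def test_bad_top_k_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="top_k"):
            rank_important_features(fitted_model, top_k=0)

    def test_planted_features_enriched_far_above_chance(self, small_sim, fitted_model):
        # tiny 60-classifier ensemble: coverage is sparse, so only demand strong
        # enrichment over the 20/300 chance rate (full-scale recovery is checked
        # at the standard study condition elsewhere)
        top = rank_important_features(fitted_model, top_k=20)
        hits = len(set(top.feature_name) & set(small_sim.truth))
        assert hits / 20 >= 0.25
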