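import numpy as np
import pytest

from deepcentroid import (
    FeatureMatrix,
    LabelVector,
    RunConfig,
    SimScenario,
    augment_features,
    fit_cascade,
    mcc_score,
    predict,
    random_scan,
    resample_balanced,
    simulate,
    simulate_multiomics,
    train_layer,
    zscore_apply,
    zscore_fit,
    zscore_fit_apply,
)


class TestZscore:
    def test_two_point_column(self):
        Z, _ = zscore_fit_apply(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        Z, _ = zscore_fit_apply(np.array([[3.0], [3.0], [3.0]]))
        np.testing.assert_array_equal(Z[:, 0], [0.0, 0.0, 0.0])

    def test_new_data_uses_training_statistics(self):
        train = np.array([[0.0], [2.0]])
        stats = zscore_fit(train)
        held_out = np.array([[4.0]])
        np.testing.assert_allclose(zscore_apply(stats, held_out), [[3.0]])  # (4-1)/1

    def test_population_denominator(self):
        stats = zscore_fit(np.array([[0.0], [1.0], [2.0]]))
        assert stats.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))


class TestResampleBalanced:
    def test_minority_composition_at_default_coefficient(self):
        y = np.array([1] * 30 + [0] * 70)
        split = resample_balanced(y, 0.65, rng=0)
        assert len(split.train_indices) == 100
        assert int(np.sum(y[split.train_indices] == 1)) == 65
        assert int(np.sum(y[split.train_indices] == 0)) == 35

    def test_balanced_input_at_half_coefficient(self):
        y = np.array([1] * 40 + [0] * 40)
        split = resample_balanced(y, 0.5, rng=1)
        assert int(np.sum(y[split.train_indices] == 1)) == 40

    def test_positive_anchor_flag(self):
        y = np.array([1] * 70 + [0] * 30)  # positives are the majority
        split = resample_balanced(y, 0.65, rng=2, coefficient_class="positive")
        assert int(np.sum(y[split.train_indices] == 1)) == 65

    def test_seed_determinism(self):
        y = np.array([1] * 10 + [0] * 20)
        a = resample_balanced(y, 0.65, rng=7)
        b = resample_balanced(y, 0.65, rng=7)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)
        np.testing.assert_array_equal(a.oob_indices, b.oob_indices)

    def test_oob_never_drawn_many_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            split = resample_balanced(y, float(rng.uniform(0.3, 0.8)), rng=rng)
            assert split.oob_indices.size > 0
            assert np.intersect1d(split.train_indices, split.oob_indices).size == 0
            assert y[split.train_indices].min() == 0 and y[split.train_indices].max() == 1

    def test_bad_coefficient_rejected(self):
        with pytest.raises(ValueError, match="coefficient"):
            resample_balanced(np.array([0, 1, 0, 1]), 1.0)


def _layer_inputs(seed=0, n=60, p=200, informative=15):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 3) + [0] * (n - n // 3))
    X = rng.normal(size=(n, p))
    X[y == 1, :informative] += 1.2
    X = X[:, rng.permutation(p)]
    return X, y


class TestTrainLayer:
    def test_planted_signal_gives_survivors_and_positive_layer_mcc(self):
        X, y = _layer_inputs()
        plan = random_scan(X.shape[1], 40, 5, 30, seed=1)
        cfg = RunConfig(n_feature_sets=40, set_size_min=5, set_size_max=30)
        layer = train_layer(X, y, plan.feature_sets, cfg, np.random.default_rng(0))
        assert len(layer.classifiers) >= 1
        assert layer.val_mcc > 0
        assert layer.n_pruned + len(layer.classifiers) == layer.n_trained

    def test_threshold_minus_one_prunes_nothing(self):
        X, y = _layer_inputs(seed=1)
        plan = random_scan(X.shape[1], 30, 5, 20, seed=2)
        cfg = RunConfig(n_feature_sets=30, set_size_min=5, set_size_max=20, prune_threshold=-1.0)
        layer = train_layer(X, y, plan.feature_sets, cfg, np.random.default_rng(0))
        assert layer.n_pruned == 0

    def test_noise_labels_prune_heavily(self):
        """With permuted labels, at least half the classifiers die at threshold 0."""
        frac = []
        for s in range(10):
            X, y = _layer_inputs(seed=s)
            y = np.random.default_rng(s).permutation(y)
            plan = random_scan(X.shape[1], 40, 5, 30, seed=s)
            cfg = RunConfig(n_feature_sets=40, set_size_min=5, set_size_max=30)
            layer = train_layer(X, y, plan.feature_sets, cfg, np.random.default_rng(s))
            frac.append(layer.n_pruned / layer.n_trained)
        assert np.mean(frac) >= 0.5

    def test_all_pruned_is_hard_error(self):
        X, y = _layer_inputs(seed=2)
        plan = random_scan(X.shape[1], 10, 5, 20, seed=3)
        cfg = RunConfig(n_feature_sets=10, set_size_min=5, set_size_max=20, prune_threshold=1.0)
        with pytest.raises(RuntimeError, match="threshold 1.0"):
            train_layer(X, y, plan.feature_sets, cfg, np.random.default_rng(0))


class TestAugmentFeatures:
    def _layer(self):
        X, y = _layer_inputs(seed=4)
        plan = random_scan(X.shape[1], 20, 5, 20, seed=4)
        cfg = RunConfig(n_feature_sets=20, set_size_min=5, set_size_max=20)
        return train_layer(X, y, plan.feature_sets, cfg, np.random.default_rng(1)), X

    def test_width_is_survivors_plus_reinjected(self):
        layer, X = self._layer()
        reinjected = X[:, :37]
        out = augment_features(layer, X, reinjected)
        assert out.shape == (X.shape[0], len(layer.classifiers) + 37)

    def test_no_reinjection_gives_score_columns_only(self):
        layer, X = self._layer()
        out = augment_features(layer, X, None)
        assert out.shape == (X.shape[0], len(layer.classifiers))

    def test_bit_identical_on_repeat(self):
        layer, X = self._layer()
        a = augment_features(layer, X, X[:, :10])
        b = augment_features(layer, X, X[:, :10])
        np.testing.assert_array_equal(a, b)


class TestFitCascade:
    def test_converges_within_max_layers_with_stop_reason(self, fitted_model, fast_config):
        assert 1 <= fitted_model.n_layers <= fast_config.max_layers
        assert fitted_model.stop_reason in ("no_improvement", "max_layers")

    def test_retained_layer_mccs_strictly_increase_at_zero_patience(self, fitted_model):
        vals = [layer.val_mcc for layer in fitted_model.layers]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_seeded_refit_is_identical(self, small_sim, fast_config):
        m1 = fit_cascade(small_sim.train_X, small_sim.train_y, fast_config)
        m2 = fit_cascade(small_sim.train_X, small_sim.train_y, fast_config)
        assert m1.n_layers == m2.n_layers
        for l1, l2 in zip(m1.layers, m2.layers):
            assert len(l1.classifiers) == len(l2.classifiers)
            assert l1.val_mcc == l2.val_mcc
        p1 = predict(m1, small_sim.independent_X)
        p2 = predict(m2, small_sim.independent_X)
        np.testing.assert_array_equal(p1.probability_positive, p2.probability_positive)

    def test_max_layers_one_trains_single_layer(self, small_sim, fast_config):
        m = fit_cascade(small_sim.train_X, small_sim.train_y, fast_config.replace(max_layers=1))
        assert m.n_layers == 1
        assert m.stop_reason == "max_layers"

    def test_pruning_invariant_all_layers(self, fitted_model):
        for layer in fitted_model.layers:
            for lc in layer.classifiers:
                assert lc.val_mcc > fitted_model.config.prune_threshold

    def test_oob_never_in_own_training_multiset(self, fitted_model):
        for layer in fitted_model.layers:
            for lc in layer.classifiers:
                assert np.intersect1d(lc.split.train_indices, lc.split.oob_indices).size == 0

    def test_two_distance_mode_and_correlation_distance_run(self, small_sim, fast_config):
        cfg = fast_config.replace(score_mode="two_distance", distance="correlation", max_layers=2)
        m = fit_cascade(small_sim.train_X, small_sim.train_y, cfg)
        res = predict(m, small_sim.independent_X)
        assert np.all((res.probability_positive >= 0) & (res.probability_positive <= 1))


class TestMultiOmicsFusion:
    @pytest.mark.parametrize("fusion", ["concatenate", "secondary_reinject"])
    def test_fusion_modes_run_end_to_end(self, fusion):
        sc = SimScenario(n_samples=60, n_features=150, n_informative=15, seed=5)
        sim = simulate_multiomics(sc, n_features_secondary=80, shared_signal_fraction=1.0)
        cfg = RunConfig(
            n_feature_sets=40, set_size_min=5, set_size_max=25, max_layers=3,
            fusion=fusion, seed=5,
        )
        m = fit_cascade(sim.train_X, sim.train_y, cfg, X2=sim.secondary_X)
        res = predict(m, sim.train_X, X2_new=sim.secondary_X)
        assert mcc_score(sim.train_y.labels, res.label) > 0

    def test_fusion_not_worse_than_primary_alone(self):
        """Adding a class-informative secondary layer should not cost performance."""
        from deepcentroid import repeated_cv

        diffs = []
        for s in range(5):
            sc = SimScenario(n_samples=100, n_features=300, n_informative=20, seed=s)
            sim = simulate_multiomics(sc, n_features_secondary=150, shared_signal_fraction=1.0)
            cfg = RunConfig(n_feature_sets=60, set_size_min=5, set_size_max=30, max_layers=4)

            def fusion_fitter(X, y, config, seed, _sim=sim):
                from deepcentroid import cascade

                X2 = _sim.secondary_X.subset_samples(list(X.sample_ids))
                model = cascade.fit_cascade(X, y, config.replace(seed=seed), X2=X2)

                def _p(Xte, _m=model, _X2=_sim.secondary_X):
                    res = predict(_m, Xte, X2_new=_X2.subset_samples(list(Xte.sample_ids)))
                    return res.probability_positive, res.label

                return _p

            base = repeated_cv(sim.train_X, sim.train_y, cfg, k=5, repeats=1, seed=s)
            fused = repeated_cv(sim.train_X, sim.train_y, cfg, k=5, repeats=1, seed=s, fitter=fusion_fitter)
            diffs.append(fused.aggregate["mean_mcc"] - base.aggregate["mean_mcc"])
        assert np.mean(diffs) >= -0.05
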