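"""Dilated causal network, CV training, model selection, ensembling."""

import numpy as np
import pytest

from strainpheno.classifier import (
    TrainedEnsemble,
    assign_group_folds,
    build_network,
    predict_ensemble,
    select_model,
    train_cv,
)
from strainpheno.io_preprocess import normalize_time
from strainpheno.synthetic import simulate_subject
from strainpheno.tcn import DilatedCausalNet, NetworkConfig, train_network


class TestBuildNetwork:
    def test_receptive_field_formula_and_empirical_support(self):
        cfg = NetworkConfig(n_feature_maps=8, n_levels=4, kernel_size=3, dropout=0.0, seed=0)
        net = build_network(cfg, input_shape=(6, 101))
        assert net.receptive_field == 63
        # empirical oracle: gradient support of the last-time activation
        T = 101
        X = np.random.default_rng(0).normal(size=(1, 6, T))
        base_logits, cache = net.forward(X)
        h_last = cache["h_final"][0, :, -1].copy()
        support = []
        for t in range(T):
            Xp = X.copy()
            Xp[0, :, t] += 1e-3
            _, cp = net.forward(Xp)
            if np.abs(cp["h_final"][0, :, -1] - h_last).max() > 1e-12:
                support.append(t)
        assert len(support) == net.receptive_field
        assert support[-1] == T - 1

    def test_causality_future_inputs_do_not_affect_past(self):
        cfg = NetworkConfig(n_feature_maps=8, n_levels=3, kernel_size=3, dropout=0.0, seed=1)
        net = build_network(cfg, input_shape=(6, 50))
        X = np.random.default_rng(2).normal(size=(1, 6, 50))
        _, c0 = net.forward(X)
        X2 = X.copy()
        X2[0, :, 26:] = 0.0
        _, c1 = net.forward(X2)
        for blk0, blk1 in zip(c0["blocks"], c1["blocks"]):
            assert np.abs(blk0["a"][0, :, :26] - blk1["a"][0, :, :26]).max() <= 1e-6

    def test_seeded_init_is_deterministic(self):
        cfg = NetworkConfig(seed=42)
        a, b = DilatedCausalNet(cfg), DilatedCausalNet(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_output_is_probability(self):
        net = build_network(NetworkConfig(seed=0), input_shape=(6, 101))
        p = net.predict_proba(np.zeros((3, 6, 101)))
        assert np.all((p > 0) & (p < 1))

    def test_gradients_match_finite_differences(self):
        cfg = NetworkConfig(n_feature_maps=4, n_levels=2, kernel_size=3, dropout=0.0, seed=3)
        net = DilatedCausalNet(cfg)
        X = np.random.default_rng(0).normal(size=(2, 6, 20))
        _, dX = net.input_gradients(X)
        eps = 1e-6
        for (i, j, k) in [(0, 0, 0), (1, 3, 10), (0, 5, 19)]:
            Xp, Xm = X.copy(), X.copy()
            Xp[i, j, k] += eps
            Xm[i, j, k] -= eps
            num = (net.predict_logit(Xp)[i] - net.predict_logit(Xm)[i]) / (2 * eps)
            assert num == pytest.approx(dX[i, j, k], abs=1e-7)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_network(NetworkConfig(), input_shape=(0, 101))
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=1)
        with pytest.raises(ValueError):
            NetworkConfig(n_levels=0)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, toy_network):
        net, X, y = toy_network
        # toy_network fixture trains on the separable cohort
        cfg = net.config
        fresh = DilatedCausalNet(cfg)
        hist = train_network(fresh, X[:80], y[:80], X[80:], y[80:], seed=5)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_training_determinism(self, separable_cohort):
        _, X, y = separable_cohort
        cfg = NetworkConfig(n_feature_maps=4, n_levels=2, max_epochs=5, seed=9)
        runs = []
        for _ in range(2):
            net = DilatedCausalNet(cfg)
            hist = train_network(net, X[:40], y[:40], X[40:60], y[40:60], seed=2)
            runs.append((hist.train_loss, net.predict_logit(X[60:64])))
        np.testing.assert_allclose(runs[0][0], runs[1][0], atol=1e-6)
        np.testing.assert_allclose(runs[0][1], runs[1][1], atol=1e-6)


class TestGroupFolds:
    def test_ten_groups_two_per_fold(self):
        sizes = {f"g{i}": 4 for i in range(10)}
        folds = assign_group_folds(list(sizes), sizes, k=5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert list(counts) == [2] * 5

    def test_oversized_group_rejected(self):
        sizes = {"big": 30, "a": 2, "b": 2}
        with pytest.raises(ValueError, match="larger than a fold"):
            assign_group_folds(list(sizes), sizes, k=5, seed=0)


class TestTrainCV:
    def test_separable_cohort_reaches_perfect_fold_f1(self, separable_cohort):
        records, X, y = separable_cohort
        groups = [r.subject_id for r in records]  # singleton groups
        cfg = NetworkConfig(
            n_feature_maps=8, n_levels=3, kernel_size=3, dropout=0.1,
            learning_rate=3e-3, max_epochs=60, patience=20, seed=0,
        )
        ensemble, fold_f1 = train_cv(X, y, groups, cfg, k=5, seed=1)
        assert len(ensemble.members) == 5
        assert all(f == pytest.approx(1.0) for f in fold_f1)

    def test_groups_never_straddle_folds(self, separable_cohort):
        records, X, y = separable_cohort
        # pair carrier i with control i into one match group
        groups = [f"g{i // 2}" for i in range(len(records))]
        cfg = NetworkConfig(n_feature_maps=4, n_levels=2, max_epochs=2, seed=0)
        ensemble, _ = train_cv(X, y, groups, cfg, k=5, seed=3)
        assert set(ensemble.fold_assignments.values()) == set(range(5))

    def test_permutation_null_f1_is_chance_level(self, covariates, noise_free_params):
        """Shuffled labels carry no signal: mean fold F1 sits in a wide
        chance band across seeds."""
        records = []
        for i in range(100):
            ph = ["A", "B", "C", "D"][i % 4]
            records.append(
                simulate_subject("carrier", ph, covariates, seed=i, params=noise_free_params)
            )
            records.append(
                simulate_subject("control", "CONTROL", covariates, seed=10_000 + i,
                                 params=noise_free_params)
            )
        X = np.stack([normalize_time(r).matrix for r in records])
        cfg = NetworkConfig(n_feature_maps=4, n_levels=2, max_epochs=8, patience=8, seed=0)
        means = []
        for seed in (1, 2, 3):
            y = np.random.default_rng(seed).permutation([1.0, 0.0] * 100)
            groups = [f"s{i}" for i in range(len(records))]
            _, fold_f1 = train_cv(X, y, groups, cfg, k=5, seed=seed)
            means.append(np.mean(fold_f1))
        assert 0.25 <= np.mean(means) <= 0.75


class TestGridSearch:
    def test_default_grid_spans_all_axes(self):
        from strainpheno.classifier import DEFAULT_GRID, expand_grid

        configs = expand_grid()
        assert len(configs) == 2 * 3 * 2 * 2
        assert {c.n_levels for c in configs} == set(DEFAULT_GRID["n_levels"])

    def test_grid_search_prefers_the_learnable_configuration(self, separable_cohort):
        from strainpheno.classifier import grid_search

        records, X, y = separable_cohort
        groups = [r.subject_id for r in records]
        # one candidate cannot learn (zero epochs of training survive the
        # untrained init), the other can
        frozen = NetworkConfig(n_feature_maps=4, n_levels=2, max_epochs=1,
                               learning_rate=1e-9, seed=0)
        capable = NetworkConfig(n_feature_maps=8, n_levels=3, learning_rate=3e-3,
                                max_epochs=40, patience=15, seed=0)
        best, runs = grid_search(X, y, groups, [frozen, capable], k=3, seed=1)
        assert best is capable
        f1_by_cfg = {id(c): f1 for c, f1, _ in runs}
        assert f1_by_cfg[id(capable)] > f1_by_cfg[id(frozen)]


class TestSelectModel:
    C1 = NetworkConfig(n_feature_maps=8)
    C2 = NetworkConfig(n_feature_maps=16)

    def test_unique_maximum_wins(self):
        assert select_model([(self.C1, 0.80, 10_000), (self.C2, 0.90, 50_000)]) is self.C2

    def test_tie_broken_by_parameter_count(self):
        assert select_model([(self.C2, 0.90, 50_000), (self.C1, 0.90, 10_000)]) is self.C1

    def test_single_entry(self):
        assert select_model([(self.C1, 0.5, 1)]) is self.C1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class _ConstantNet:
    """Stand-in ensemble member with a fixed output probability."""

    def __init__(self, prob, config):
        self.config = config
        self.n_channels = 6
        self._logit = np.log(prob / (1 - prob))

    def predict_proba(self, X):
        return np.full(len(X), 1 / (1 + np.exp(-self._logit)))


class TestPredictEnsemble:
    def _ensemble(self, probs):
        cfg = NetworkConfig()
        members = [_ConstantNet(p, cfg) for p in probs]
        return TrainedEnsemble(members=members, config=cfg, fold_assignments={})

    def test_constant_members(self):
        ens = self._ensemble([0.6] * 5)
        assert predict_ensemble(ens, np.zeros((6, 101))) == pytest.approx(0.6)

    def test_symmetric_members_average_to_half(self):
        eps = 1e-9
        ens = self._ensemble([eps, 0.25, 0.5, 0.75, 1 - eps])
        assert predict_ensemble(ens, np.zeros((6, 101))) == pytest.approx(0.5, abs=1e-6)

    def test_identical_members_idempotent(self, toy_network):
        net, X, _ = toy_network
        ens = TrainedEnsemble(members=[net] * 5, config=net.config, fold_assignments={})
        np.testing.assert_allclose(
            predict_ensemble(ens, X[:4]), net.predict_proba(X[:4]), atol=1e-12
        )

    def test_shape_mismatch_rejected(self, toy_network):
        net, _, _ = toy_network
        ens = TrainedEnsemble(members=[net], config=net.config, fold_assignments={})
        with pytest.raises(ValueError):
            predict_ensemble(ens, np.zeros((4, 101)))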