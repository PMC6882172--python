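"""Attention, softmax head, cross-entropy, full-model passes and training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppilstm as pl
from ppilstm.exceptions import ValidationError


def small_config(**kw):
    defaults = dict(layers=4, units=3, input_size=4, dropout_in=0.0,
                    dropout_mid=0.0, seed=0)
    defaults.update(kw)
    return pl.NetworkConfig(**defaults)


class TestSoftmax:
    def test_symmetric_pair(self):
        np.testing.assert_allclose(pl.softmax([0.0, 0.0]), [0.5, 0.5])

    def test_reference_values(self):
        np.testing.assert_allclose(pl.softmax([1.0, 2.0, 3.0]),
                                   [0.0900, 0.2447, 0.6652], atol=1e-4)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6),
           st.floats(-100, 100))
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance_and_normalization(self, z, c):
        z = np.array(z)
        p = pl.softmax(z)
        assert np.all(p > 0) and np.all(p < 1 + 1e-12)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(pl.softmax(z + c), p, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pl.softmax([])


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert pl.categorical_crossentropy([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_guess_costs_ln2(self):
        assert pl.categorical_crossentropy([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2), rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_gibbs_inequality_and_kl_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        h_pq = pl.categorical_crossentropy(p, q)
        h_p = pl.categorical_crossentropy(p, p)
        kl = float((p * (np.log(p) - np.log(q))).sum())
        assert h_pq - h_p >= -1e-10
        assert h_pq == pytest.approx(h_p + kl, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pl.categorical_crossentropy([1.0, 0.0], [0.5, 0.25, 0.25])


class TestAttention:
    def test_identical_vectors_give_uniform_weights_and_identity(self, rng):
        params = pl.AttentionParams(rng.uniform(-1, 1, (3, 3)),
                                    rng.uniform(-1, 1, 3))
        H = np.tile(rng.uniform(-1, 1, 3), (5, 1))
        w, out = pl.attention_forward(H, params)
        np.testing.assert_allclose(w, np.full(5, 0.2), rtol=1e-12)
        np.testing.assert_allclose(out, H, rtol=1e-12)

    def test_single_timestep_is_identity(self, rng):
        params = pl.AttentionParams(rng.uniform(-1, 1, (3, 3)),
                                    rng.uniform(-1, 1, 3))
        H = rng.uniform(-1, 1, (1, 3))
        w, out = pl.attention_forward(H, params)
        assert w[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out, H)

    def test_weights_match_direct_reevaluation(self, rng):
        params = pl.AttentionParams(rng.uniform(-1, 1, (2, 3)),
                                    rng.uniform(-1, 1, 2))
        H = rng.uniform(-1, 1, (6, 3))
        w, out = pl.attention_forward(H, params)
        energies = np.array([params.v @ np.tanh(params.score_map @ h) for h in H])
        expect = np.exp(energies - energies.max())
        expect /= expect.sum()
        np.testing.assert_allclose(w, expect, rtol=1e-12)
        assert np.all(w >= 0) and abs(w.sum() - 1) < 1e-12
        np.testing.assert_allclose(out, 6 * w[:, None] * H, rtol=1e-12)

    def test_empty_sequence_rejected(self, rng):
        params = pl.AttentionParams(rng.uniform(-1, 1, (2, 3)),
                                    rng.uniform(-1, 1, 2))
        with pytest.raises(ValidationError):
            pl.attention_forward(np.empty((0, 3)), params)


class TestModelForward:
    def test_eval_mode_is_deterministic(self, rng):
        params = pl.init_network(small_config(dropout_in=0.15, dropout_mid=0.6))
        X = rng.uniform(-1, 1, (5, 4))
        p1 = pl.model_forward(params, X)
        p2 = pl.model_forward(params, X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_dropout_train_equals_eval(self, rng):
        params = pl.init_network(small_config())
        X = rng.uniform(-1, 1, (5, 4))
        np.testing.assert_allclose(
            pl.model_forward(params, X, train_mode=True, rng=0),
            pl.model_forward(params, X), rtol=1e-12)

    def test_seeded_dropout_replays_identically(self, rng):
        params = pl.init_network(small_config(dropout_in=0.15, dropout_mid=0.6))
        X = rng.uniform(-1, 1, (5, 4))
        p1 = pl.model_forward(params, X, train_mode=True, rng=42)
        p2 = pl.model_forward(params, X, train_mode=True, rng=42)
        p3 = pl.model_forward(params, X, train_mode=True, rng=43)
        np.testing.assert_array_equal(p1, p2)
        assert not np.array_equal(p1, p3)

    def test_wrong_feature_width_rejected(self, rng):
        params = pl.init_network(small_config())
        with pytest.raises(ValidationError):
            pl.model_forward(params, rng.uniform(-1, 1, (5, 7)))

    def test_end_to_end_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        params = pl.init_network(small_config(init_scale=0.5, seed=11))
        X = rng.uniform(-1, 1, (6, 4))
        y = rng.integers(0, 2, 6)

        def loss():
            return pl.sequence_loss(pl.model_forward(params, X), y)[0]

        probs, cache = pl.model_forward(params, X, return_cache=True)
        _, dlogits = pl.sequence_loss(probs, y)
        analytic = pl.model_backward(params, cache, dlogits)
        numeric = pl.numerical_gradient_oracle(loss, params.named_arrays())
        assert pl.max_relative_error(analytic, numeric) <= 1e-6


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, synthetic_dataset):
        cfg = small_config(input_size=18, units=4)
        tcfg = pl.TrainingConfig(epochs=2, learning_rate=0.0, seed=0)
        before = {k: v.copy() for k, v in pl.init_network(cfg).named_arrays().items()}
        res = pl.train_model(cfg, tcfg, synthetic_dataset["train"][:2])
        after = res.params.named_arrays()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_separable_dimer_reaches_low_loss(self, synthetic_dataset):
        cfg = pl.NetworkConfig(layers=4, units=8, seed=0)
        tcfg = pl.TrainingConfig(epochs=200, learning_rate=0.01, seed=0)
        res = pl.train_model(cfg, tcfg, synthetic_dataset["train"][:1])
        assert res.history.train_loss.iloc[-1] < 0.1
        assert res.history.train_loss.iloc[-1] < res.history.train_loss.iloc[0]

    def test_seeded_run_is_reproducible(self, synthetic_dataset):
        cfg = small_config(input_size=18, units=4,
                           dropout_in=0.15, dropout_mid=0.3)
        tcfg = pl.TrainingConfig(epochs=3, learning_rate=0.01, seed=5)
        h1 = pl.train_model(cfg, tcfg, synthetic_dataset["train"][:3],
                            synthetic_dataset["validation"]).history
        h2 = pl.train_model(cfg, tcfg, synthetic_dataset["train"][:3],
                            synthetic_dataset["validation"]).history
        assert h1.equals(h2)

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValidationError):
            pl.train_model(small_config(), pl.TrainingConfig(epochs=1), [])


class TestGridSearch:
    def test_single_candidate_returned_as_best(self):
        res = pl.grid_search_layers_units(
            [4], [2], {}, pl.TrainingConfig(epochs=1),
            objective=lambda m, n: 0.5)
        assert res.best == (4, 2)

    def test_stubbed_objective_finds_known_minimum(self):
        def objective(m, n):
            return abs(m - 6) * 0.1 + abs(n - 4) * 0.01 + 0.001

        res = pl.grid_search_layers_units([2, 6, 10], [2, 4, 8], {},
                                          pl.TrainingConfig(epochs=1),
                                          objective=objective)
        assert res.best == (6, 4)
        means = [m for _, m in res.ranked]
        assert means == sorted(means)

    def test_table_layout_has_dimers_plus_mean_row(self):
        def objective(m, n):
            per = [0.001 * m, 0.002 * n, 0.003]
            return float(np.mean(per)), per

        res = pl.grid_search_layers_units([2, 4], [2], {},
                                          pl.TrainingConfig(epochs=1),
                                          objective=objective)
        assert res.table.index[-1] == "mean"
        assert res.table.shape[0] == 4  # 3 dimers + mean
        for col in res.table.columns:
            np.testing.assert_allclose(res.table[col].iloc[:-1].mean(),
                                       res.table[col].iloc[-1])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            pl.grid_search_layers_units([], [2], {}, pl.TrainingConfig(epochs=1),
                                        objective=lambda m, n: 0.0)


class TestCheckpoint:
    def test_round_trip_is_bitwise_identical(self, tmp_path, synthetic_dataset):
        cfg = small_config(input_size=18, units=4)
        tcfg = pl.TrainingConfig(epochs=1, learning_rate=0.01, seed=0)
        res = pl.train_model(cfg, tcfg, synthetic_dataset["train"][:2])
        path = tmp_path / "model.npz"
        pl.save_network(path, res.params)
        loaded = pl.load_network(path)
        orig = res.params.named_arrays()
        for k, v in loaded.named_arrays().items():
            np.testing.assert_array_equal(v, orig[k])
        np.testing.assert_array_equal(loaded.feature_mean, res.params.feature_mean)
        X = synthetic_dataset["train"][0].matrix()
        np.testing.assert_array_equal(pl.model_forward(loaded, X),
                                      pl.model_forward(res.params, X))
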