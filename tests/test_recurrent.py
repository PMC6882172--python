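"""Forward recursions and hand-derived BPTT of the recurrent layers."""

import numpy as np
import pytest

import ppilstm as pl
from ppilstm.exceptions import ConfigurationError, ValidationError

from conftest import random_lstm_layer


def loop_rnn_oracle(params, X):
    """Scalar, index-by-index evaluation of the plain-RNN recursions,
    independent of the vectorized implementation."""
    T, I = X.shape
    H, K = params.hidden_size, params.output_size
    a_h = np.zeros((T, H))
    b_h = np.zeros((T, H))
    a_k = np.zeros((T, K))
    for t in range(T):
        for h in range(H):
            s = sum(params.w_xh[i, h] * X[t, i] for i in range(I))
            if t > 0:
                s += sum(params.w_hh[hp, h] * b_h[t - 1, hp] for hp in range(H))
            a_h[t, h] = s
            b_h[t, h] = np.tanh(s)
        for k in range(K):
            a_k[t, k] = sum(params.w_hk[h, k] * b_h[t, h] for h in range(H))
    return a_h, b_h, a_k


class TestRnn:
    def test_zero_weights_give_zero_trace(self):
        p = pl.RnnLayerParams(np.zeros((2, 3)), np.zeros((3, 3)), np.zeros((3, 1)))
        tr = pl.rnn_forward(p, np.ones((4, 2)))
        assert np.all(tr.a_h == 0) and np.all(tr.b_h == 0) and np.all(tr.a_k == 0)

    def test_linear_scalar_unrolling(self):
        # identity activation, all weights 1: b^1 = 1, b^2 = x^2 + b^1 = 2
        p = pl.RnnLayerParams([[1.0]], [[1.0]], [[1.0]], activation="identity")
        tr = pl.rnn_forward(p, [[1.0], [1.0]])
        assert tr.b_h[0, 0] == 1.0
        assert tr.b_h[1, 0] == 2.0
        assert tr.a_k[1, 0] == 2.0

    def test_matches_scalar_loop_oracle(self, rng):
        p = pl.init_rnn_layer(2, 3, 2, rng, scale=0.8)
        X = rng.uniform(-1, 1, size=(4, 2))
        tr = pl.rnn_forward(p, X)
        a_h, b_h, a_k = loop_rnn_oracle(p, X)
        np.testing.assert_allclose(tr.a_h, a_h, rtol=1e-12)
        np.testing.assert_allclose(tr.b_h, b_h, rtol=1e-12)
        np.testing.assert_allclose(tr.a_k, a_k, rtol=1e-12)

    def test_backward_zero_deltas(self, rng):
        p = pl.init_rnn_layer(2, 3, 2, rng)
        tr = pl.rnn_forward(p, rng.uniform(-1, 1, (3, 2)))
        res = pl.rnn_backward(tr, np.zeros((3, 2)), p)
        assert all(np.all(g == 0) for g in res.gradients.values())

    def test_backward_single_timestep_has_no_recurrent_term(self, rng):
        p = pl.init_rnn_layer(2, 3, 2, rng, scale=0.8)
        X = rng.uniform(-1, 1, (1, 2))
        tr = pl.rnn_forward(p, X)
        D = rng.normal(size=(1, 2))
        res = pl.rnn_backward(tr, D, p)
        expected = (1 - np.tanh(tr.a_h[0]) ** 2) * (D[0] @ p.w_hk.T)
        np.testing.assert_allclose(res.hidden_deltas[0], expected, rtol=1e-12)

    def test_backward_matches_finite_differences(self, rng):
        p = pl.init_rnn_layer(2, 3, 2, rng, scale=0.8)
        X = rng.uniform(-1, 1, (4, 2))
        D = rng.normal(size=(4, 2))

        def loss():
            return float((pl.rnn_forward(p, X).a_k * D).sum())

        res = pl.rnn_backward(pl.rnn_forward(p, X), D, p)
        num = pl.numerical_gradient_oracle(loss, p.named_arrays())
        assert pl.max_relative_error(res.gradients, num) <= 1e-6

    def test_shape_mismatch_rejected(self, rng):
        p = pl.init_rnn_layer(2, 3, 2, rng)
        with pytest.raises(ValidationError):
            pl.rnn_forward(p, np.ones((3, 5)))
        with pytest.raises(ValidationError):
            pl.rnn_forward(p, np.array([[np.nan, 1.0]]))


class TestLstmForward:
    def test_zero_weights_gates_half_state_zero(self):
        layer = random_lstm_layer(2, 3, scale=0.0)
        tr = pl.lstm_layer_forward(layer, np.ones((5, 2)))
        assert np.allclose(tr.b_i, 0.5) and np.allclose(tr.b_f, 0.5)
        assert np.allclose(tr.b_o, 0.5)
        assert np.all(tr.s == 0) and np.all(tr.b == 0)

    def test_single_cell_hand_evaluation(self):
        # C = I = 1, every weight 0.5, x = 1, zero initial state:
        # s^1 = sigma(0.5) * tanh(0.5) ~ 0.2876, b^1 ~ 0.1836
        shapes = {"w_xi": (1, 1), "w_hi": (1, 1), "w_ci": (1,),
                  "w_xf": (1, 1), "w_hf": (1, 1), "w_cf": (1,),
                  "w_xc": (1, 1), "w_hc": (1, 1),
                  "w_xo": (1, 1), "w_ho": (1, 1), "w_co": (1,)}
        layer = pl.LstmLayerParams(**{k: np.full(s, 0.5) for k, s in shapes.items()})
        tr = pl.lstm_layer_forward(layer, [[1.0]])
        assert tr.s[0, 0] == pytest.approx(0.2876, abs=1e-4)
        assert tr.b[0, 0] == pytest.approx(0.1836, abs=1e-4)

    def test_saturated_gates_give_perfect_memory(self):
        # forget gate ~ 1 and input gate ~ 0 (large biases): the state is a
        # constant-error carousel, s^t = s^0 for all t
        layer = random_lstm_layer(2, 3, scale=0.3)
        layer.b_f[:] = 50.0
        layer.b_i[:] = -50.0
        s0 = np.array([0.3, -0.7, 1.1])
        tr = pl.lstm_layer_forward(layer, np.ones((6, 2)),
                                   initial_state=(s0, np.zeros(3)))
        np.testing.assert_allclose(tr.s, np.tile(s0, (6, 1)), atol=1e-12)

    def test_state_recursion_conserved(self, rng):
        # every stored state satisfies s^t = b_f^t s^{t-1} + b_i^t g(a_c^t)
        for seed in range(5):
            layer = random_lstm_layer(3, 4, seed=seed, scale=0.8)
            tr = pl.lstm_layer_forward(layer, rng.uniform(-2, 2, (7, 3)))
            for t in range(tr.T):
                lhs = tr.s[t]
                rhs = tr.b_f[t] * tr.prev_s(t) + tr.b_i[t] * np.tanh(tr.a_c[t])
                np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-15)

    def test_width_mismatch_rejected(self):
        layer = random_lstm_layer(2, 3)
        with pytest.raises(ValidationError):
            pl.lstm_layer_forward(layer, np.ones((4, 3)))


class TestLstmBackward:
    def test_zero_upstream_gives_zero_gradients(self, rng):
        layer = random_lstm_layer(2, 3)
        tr = pl.lstm_layer_forward(layer, rng.uniform(-1, 1, (4, 2)))
        res = pl.lstm_layer_backward(tr, np.zeros((4, 3)), layer)
        assert all(np.all(g == 0) for g in res.gradients.values())
        assert np.all(res.input_deltas == 0)

    def test_final_timestep_state_error_formula(self, rng):
        # at t = T there are no t+1 terms:
        # eps_s^T = b_o^T h'(s^T) eps_c^T + w_co d_o^T
        layer = random_lstm_layer(2, 3, scale=0.6)
        tr = pl.lstm_layer_forward(layer, rng.uniform(-1, 1, (4, 2)))
        U = rng.normal(size=(4, 3))
        res = pl.lstm_layer_backward(tr, U, layer)
        T = 3
        expected = (tr.b_o[T] * (1 - np.tanh(tr.s[T]) ** 2) * res.eps_c[T]
                    + layer.w_co * res.d_o[T])
        np.testing.assert_allclose(res.eps_s[T], expected, rtol=1e-12)

    @pytest.mark.parametrize("current_state_peep", [True, False])
    def test_matches_finite_differences(self, current_state_peep):
        rng = np.random.default_rng(3)
        layer = random_lstm_layer(
            1, 1, seed=5, scale=0.7,
            output_gate_peeks_current_state=current_state_peep)
        X = rng.uniform(-1, 1, (3, 1))
        U = rng.normal(size=(3, 1))

        def loss():
            return float((pl.lstm_layer_forward(layer, X).b * U).sum())

        res = pl.lstm_layer_backward(pl.lstm_layer_forward(layer, X), U, layer)
        num = pl.numerical_gradient_oracle(loss, layer.named_arrays())
        assert pl.max_relative_error(res.gradients, num) <= 1e-6
        # per-array is just as clean on a healthy single layer
        assert pl.max_relative_error(res.gradients, num,
                                     aggregate="per_array") <= 1e-6

    def test_output_gate_peephole_convention_changes_forward(self, rng):
        """The current-state and previous-state output-gate peepholes are
        genuinely different layers (but agree at t=1 only through s^0=0...
        they differ once the state is nonzero)."""
        cur = random_lstm_layer(2, 2, seed=1, scale=0.8)
        prev = random_lstm_layer(2, 2, seed=1, scale=0.8,
                                 output_gate_peeks_current_state=False)
        X = rng.uniform(-1, 1, (4, 2))
        b_cur = pl.lstm_layer_forward(cur, X).b
        b_prev = pl.lstm_layer_forward(prev, X).b
        assert not np.allclose(b_cur, b_prev)

    def test_mismatched_length_rejected(self, rng):
        layer = random_lstm_layer(2, 3)
        tr = pl.lstm_layer_forward(layer, rng.uniform(-1, 1, (4, 2)))
        with pytest.raises(ValidationError):
            pl.lstm_layer_backward(tr, np.zeros((5, 3)), layer)


class TestBigBlock:
    def test_zero_upper_layer_is_identity_like_shortcut(self, rng):
        lower = random_lstm_layer(2, 3, seed=0, scale=0.6)
        upper = random_lstm_layer(3, 3, seed=1, scale=0.0)
        block = pl.BigBlockParams(lower=lower, upper=upper)
        X = rng.uniform(-1, 1, (4, 2))
        tr = pl.big_block_forward(block, X)
        np.testing.assert_allclose(tr.residual_output,
                                   pl.lstm_layer_forward(lower, X).b)

    def test_zero_everything_gives_zero_output(self):
        block = pl.BigBlockParams(lower=random_lstm_layer(2, 3, scale=0.0),
                                  upper=random_lstm_layer(3, 3, scale=0.0))
        tr = pl.big_block_forward(block, np.zeros((3, 2)))
        assert np.all(tr.residual_output == 0)

    def test_compositional_oracle(self, rng):
        # block forward == lower forward, then upper forward, plus the sum
        lower = random_lstm_layer(3, 2, seed=2, scale=0.6)
        upper = random_lstm_layer(2, 2, seed=3, scale=0.6)
        block = pl.BigBlockParams(lower=lower, upper=upper)
        X = rng.uniform(-1, 1, (3, 3))
        tr = pl.big_block_forward(block, X)
        b_low = pl.lstm_layer_forward(lower, X).b
        b_up = pl.lstm_layer_forward(upper, b_low).b
        np.testing.assert_allclose(tr.residual_output, b_low + b_up, rtol=1e-12)

    def test_zero_jacobian_upper_passes_error_through_unchanged(self, rng):
        # all-zero upper weights: the through-path Jacobian is exactly zero,
        # so the lower layer's upstream error equals the residual-sum error
        lower = random_lstm_layer(2, 3, seed=0, scale=0.6)
        upper = random_lstm_layer(3, 3, seed=1, scale=0.0)
        block = pl.BigBlockParams(lower=lower, upper=upper)
        X = rng.uniform(-1, 1, (4, 2))
        tr = pl.big_block_forward(block, X)
        U = rng.normal(size=(4, 3))
        res = pl.big_block_backward(block, tr, U)
        np.testing.assert_allclose(res.lower.eps_c[-1], U[-1], rtol=1e-12)
        lower_alone = pl.lstm_layer_backward(tr.lower, U, lower)
        for k in lower_alone.gradients:
            np.testing.assert_allclose(res.lower.gradients[k],
                                       lower_alone.gradients[k], rtol=1e-10)

    def test_backward_matches_finite_differences(self, rng):
        lower = random_lstm_layer(2, 2, seed=4, scale=0.6)
        upper = random_lstm_layer(2, 2, seed=5, scale=0.6)
        block = pl.BigBlockParams(lower=lower, upper=upper)
        X = rng.uniform(-1, 1, (3, 2))
        U = rng.normal(size=(3, 2))

        def loss():
            return float((pl.big_block_forward(block, X).residual_output * U).sum())

        res = pl.big_block_backward(block, pl.big_block_forward(block, X), U)
        num = pl.numerical_gradient_oracle(loss, block.named_arrays())
        assert pl.max_relative_error(res.named_gradients(), num) <= 1e-6

    def test_width_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pl.BigBlockParams(lower=random_lstm_layer(2, 3),
                              upper=random_lstm_layer(3, 4))


class TestStack:
    def test_odd_depth_final_layer_has_no_shortcut(self, rng):
        layers = [random_lstm_layer(2 if i == 0 else 2, 2, seed=i, scale=0.5)
                  for i in range(3)]
        X = rng.uniform(-1, 1, (3, 2))
        st = pl.stack_forward(layers, X, residual=True)
        block = pl.BigBlockParams(lower=layers[0], upper=layers[1])
        mid = pl.big_block_forward(block, X).residual_output
        final = pl.lstm_layer_forward(layers[2], mid).b
        np.testing.assert_allclose(st.output, final, rtol=1e-12)

    def test_residual_flag_off_is_plain_chain(self, rng):
        layers = [random_lstm_layer(2, 2, seed=i, scale=0.5) for i in range(4)]
        X = rng.uniform(-1, 1, (3, 2))
        st = pl.stack_forward(layers, X, residual=False)
        h = X
        for lay in layers:
            h = pl.lstm_layer_forward(lay, h).b
        np.testing.assert_allclose(st.output, h, rtol=1e-12)


class TestNumericalOracle:
    def test_quadratic_closed_form(self):
        w = np.array([3.0])

        def loss():
            return float(w[0] ** 2)

        grad = pl.numerical_gradient_oracle(loss, {"w": w})
        assert grad["w"][0] == pytest.approx(6.0, abs=1e-8)

    def test_unused_weight_gets_zero_gradient(self):
        w = np.array([3.0])
        unused = np.array([1.0, 2.0])

        def loss():
            return float(w[0] ** 2)

        grad = pl.numerical_gradient_oracle(loss, {"w": w, "unused": unused})
        assert np.all(grad["unused"] == 0)

    def test_nondeterministic_loss_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            pl.numerical_gradient_oracle(lambda: rng.random(), {"w": np.ones(1)})

    def test_eps_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            pl.numerical_gradient_oracle(lambda: 0.0, {"w": np.ones(1)}, eps=1e-2)
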