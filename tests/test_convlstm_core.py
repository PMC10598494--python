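"""The convolutional LSTM cell against independent oracles.

Three routes verify the cell: (1) a fully hand-evaluated scalar case on a
1x1 grid with 1x1 kernels, where every gate is a plain logistic function;
(2) a per-gate reference built on scipy.signal.correlate2d; (3) the
vectorized trainable layer, which must match the functional core exactly.
"""

import math

import numpy as np
import pytest
from scipy import signal

from ctmonitor import nn
from ctmonitor.convlstm_core import (
    CellState,
    ConvLSTMParams,
    cell_step,
    gate_forget,
    gate_input,
    gate_output,
    sequence_forward,
)


def scalar_params(w_h, w_x, b, hidden=1):
    """1x1-kernel params with identical values in all four gates unless mapped."""
    w = np.zeros((1, 1, 2, 1))
    w[0, 0, 0, 0] = w_h
    w[0, 0, 1, 0] = w_x
    bias = np.array([b], dtype=float)
    return ConvLSTMParams(w_i=w.copy(), w_f=w.copy(), w_c=w.copy(), w_o=w.copy(),
                          b_i=bias.copy(), b_f=bias.copy(), b_c=bias.copy(),
                          b_o=bias.copy())


def random_params(rng, k, cin, hidden):
    return ConvLSTMParams.init(rng, k, cin, hidden, forget_bias=0.0)


class TestGates:
    def test_zero_parameters_give_half(self):
        p = scalar_params(0.0, 0.0, 0.0)
        x = np.full((4, 4, 1), 0.3)
        h = np.full((4, 4, 1), -0.7)
        for gate in (gate_forget, gate_input, gate_output):
            np.testing.assert_allclose(gate(x, h, p), 0.5)

    def test_scalar_forget_gate(self):
        # w_f = [1, 1] over [h, x] = [0.5, 0.25] -> sigmoid(0.75)
        p = scalar_params(1.0, 1.0, 0.0)
        x = np.full((1, 1, 1), 0.25)
        h = np.full((1, 1, 1), 0.5)
        expected = 1.0 / (1.0 + math.exp(-0.75))
        np.testing.assert_allclose(gate_forget(x, h, p)[0, 0, 0], expected, atol=1e-12)

    def test_scalar_negative_weights(self):
        p = scalar_params(-1.0, -1.0, 0.0)
        x = np.full((1, 1, 1), 0.25)
        h = np.full((1, 1, 1), 0.5)
        expected = 1.0 / (1.0 + math.exp(0.75))
        np.testing.assert_allclose(gate_input(x, h, p)[0, 0, 0], expected, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self, rng):
        p = random_params(rng, 3, 2, 4)
        x = rng.normal(size=(6, 6, 2)) * 3
        h = rng.normal(size=(6, 6, 4)) * 3
        for gate in (gate_forget, gate_input, gate_output):
            g = gate(x, h, p)
            assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_gate_matches_scipy_reference(self, rng):
        p = random_params(rng, 3, 1, 2)
        x = rng.normal(size=(5, 5, 1))
        h = rng.normal(size=(5, 5, 2))
        a = np.concatenate([h, x], axis=-1)
        ref = np.zeros((5, 5, 2))
        for f in range(2):
            for c in range(3):
                ref[:, :, f] += signal.correlate2d(a[:, :, c], p.w_f[:, :, c, f],
                                                   mode="same", boundary="fill")
            ref[:, :, f] += p.b_f[f]
        ref = 1.0 / (1.0 + np.exp(-ref))
        np.testing.assert_allclose(gate_forget(x, h, p), ref, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        p = random_params(rng, 3, 1, 2)
        with pytest.raises(ValueError, match="aligned"):
            gate_forget(np.zeros((4, 4, 1)), np.zeros((5, 5, 2)), p)


class TestCellStep:
    def test_scalar_hand_evaluation(self):
        """Full scalar oracle: every gate written out in plain math."""
        w_h, w_x, b = 0.8, -0.4, 0.1
        p = scalar_params(w_h, w_x, b)
        # give each gate distinct parameters
        p.w_i[0, 0, 0, 0], p.w_i[0, 0, 1, 0], p.b_i[0] = 0.3, 0.7, -0.2
        p.w_o[0, 0, 0, 0], p.w_o[0, 0, 1, 0], p.b_o[0] = -0.5, 0.2, 0.4
        p.w_c[0, 0, 0, 0], p.w_c[0, 0, 1, 0], p.b_c[0] = 1.1, -0.9, 0.0
        h0, c0, x = 0.37, -0.21, 0.63
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        f = sig(w_h * h0 + w_x * x + b)
        i = sig(0.3 * h0 + 0.7 * x - 0.2)
        o = sig(-0.5 * h0 + 0.2 * x + 0.4)
        g = math.tanh(1.1 * h0 - 0.9 * x)
        c1 = f * c0 + i * g
        h1 = o * max(c1, 0.0)
        state = cell_step(
            np.full((1, 1, 1), x),
            CellState(h=np.full((1, 1, 1), h0), c=np.full((1, 1, 1), c0)),
            p,
        )
        np.testing.assert_allclose(state.c[0, 0, 0], c1, atol=1e-12)
        np.testing.assert_allclose(state.h[0, 0, 0], h1, atol=1e-12)

    def test_saturated_gates_preserve_cell(self, rng):
        """f -> 1, i -> 0 makes the update a pure carry of c."""
        p = random_params(rng, 3, 1, 2)
        p.b_f += 30.0
        p.b_i -= 30.0
        c0 = rng.normal(size=(5, 5, 2))
        h0 = rng.normal(size=(5, 5, 2))
        x = rng.normal(size=(5, 5, 1))
        state = cell_step(x, CellState(h=h0, c=c0), p)
        np.testing.assert_allclose(state.c, c0, atol=1e-6)

    def test_zero_state_zero_candidate_weights(self, rng):
        p = random_params(rng, 3, 1, 2)
        p.w_c[:] = 0.0
        p.b_c[:] = 0.0
        state = cell_step(np.ones((4, 4, 1)), CellState.zeros(4, 4, 2), p)
        np.testing.assert_allclose(state.c, 0.0, atol=1e-15)
        np.testing.assert_allclose(state.h, 0.0, atol=1e-15)

    def test_relu_output_keeps_hidden_nonnegative(self, rng):
        p = random_params(rng, 3, 2, 3)
        state = cell_step(rng.normal(size=(6, 6, 2)),
                          CellState(h=rng.normal(size=(6, 6, 3)),
                                    c=rng.normal(size=(6, 6, 3))), p)
        assert np.all(state.h >= 0.0)


class TestSequenceForward:
    def test_single_frame_equals_one_step(self, rng):
        p = random_params(rng, 3, 1, 2)
        x = rng.normal(size=(1, 5, 5, 1))
        out = sequence_forward(x, p, return_sequence=False)
        step = cell_step(x[0], CellState.zeros(5, 5, 2), p)
        np.testing.assert_array_equal(out, step.h)

    def test_equals_explicit_loop(self, rng):
        p = random_params(rng, 3, 2, 3)
        x = rng.normal(size=(6, 4, 4, 2))
        out = sequence_forward(x, p, return_sequence=True)
        state = CellState.zeros(4, 4, 3)
        for t in range(6):
            state = cell_step(x[t], state, p)
            np.testing.assert_array_equal(out[t], state.h)

    def test_constant_input_hidden_converges(self, rng):
        p = random_params(rng, 3, 1, 2)
        x = np.repeat(rng.random(size=(1, 5, 5, 1)), 10, axis=0)
        out = sequence_forward(x, p, return_sequence=True)
        deltas = [np.linalg.norm(out[t + 1] - out[t]) for t in range(9)]
        assert deltas[-1] < deltas[2]

    def test_empty_sequence_raises(self, rng):
        p = random_params(rng, 3, 1, 2)
        with pytest.raises(ValueError, match="non-empty"):
            sequence_forward(np.zeros((0, 4, 4, 1)), p)


class TestLayerEquivalence:
    """The vectorized trainable layer must reproduce the functional core."""

    @pytest.mark.parametrize("out_act", ["relu", "tanh"])
    def test_layer_matches_core(self, rng, out_act):
        layer = nn.ConvLSTM2D(3, 3, return_sequences=True, output_activation=out_act)
        layer.build((4, 6, 6, 2), rng)
        x = rng.normal(size=(2, 4, 6, 6, 2))
        out = layer.forward(x)
        p = layer.to_core_params()
        for s in range(2):
            ref = sequence_forward(x[s], p, return_sequence=True,
                                   output_activation=out_act)
            np.testing.assert_allclose(out[s], ref, atol=1e-6)

    def test_fused_round_trip(self, rng):
        p = ConvLSTMParams.init(rng, 3, 2, 4)
        w, b = p.fused()
        p2 = ConvLSTMParams.from_fused(w, b)
        np.testing.assert_array_equal(p.w_c, p2.w_c)
        np.testing.assert_array_equal(p.b_o, p2.b_o)
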