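"""Convolutional LSTM cell, written out gate by gate.

The cell follows the standard LSTM gating discipline, with every gate
computed as a 2-D convolution over the channel-wise concatenation of the
previous hidden state and the current input frame, ``[h_{t-1}, x_t]``:

    f_t = sigmoid(w_f * [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(w_i * [h_{t-1}, x_t] + b_i)        (input gate)
    o_t = sigmoid(w_o * [h_{t-1}, x_t] + b_o)        (output gate)
    g_t = tanh   (w_c * [h_{t-1}, x_t] + b_c)        (cell candidate)
    c_t = f_t . c_{t-1} + i_t . g_t
    h_t = o_t . act(c_t)

where ``*`` is a "same"-padded stride-1 convolution and ``.`` is the
elementwise product.  There are no peephole connections.  The output
activation ``act`` defaults to ReLU (the activation assigned to the
recurrent convolutional blocks of the frame predictor) and can be set to
the classical tanh.

This module is purely functional and single-sample; it is the reference
core that the trainable :class:`ctmonitor.nn.layers.ConvLSTM2D` layer must
reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.conv import conv_forward

__all__ = [
    "ConvLSTMParams",
    "CellState",
    "gate_forget",
    "gate_input",
    "gate_output",
    "cell_step",
    "sequence_forward",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _activation(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh
    if name == "linear":
        return lambda z: z
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class ConvLSTMParams:
    """Per-gate convolution kernels and biases.

    Each kernel has shape ``(k, k, in_channels + hidden_channels,
    hidden_channels)`` and is applied to the concatenation
    ``[h_{t-1}, x_t]`` (hidden state first).
    """

    w_i: np.ndarray
    w_f: np.ndarray
    w_c: np.ndarray
    w_o: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        ref = self.w_i.shape
        for name in ("w_f", "w_c", "w_o"):
            if getattr(self, name).shape != ref:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {ref}")
        for name in ("b_i", "b_f", "b_c", "b_o"):
            if getattr(self, name).shape != (ref[-1],):
                raise ValueError(f"{name} must have shape ({ref[-1]},)")
        for name in ("w_i", "w_f", "w_c", "w_o", "b_i", "b_f", "b_c", "b_o"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_channels(self) -> int:
        return self.w_i.shape[-1]

    @property
    def in_channels(self) -> int:
        return self.w_i.shape[-2] - self.w_i.shape[-1]

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        kernel_size: int,
        in_channels: int,
        hidden_channels: int,
        forget_bias: float = 1.0,
    ) -> "ConvLSTMParams":
        """Glorot-uniform kernels, zero biases (forget-gate bias offset)."""
        fan_in = kernel_size * kernel_size * (in_channels + hidden_channels)
        limit = np.sqrt(6.0 / (fan_in + hidden_channels))
        shape = (kernel_size, kernel_size, in_channels + hidden_channels, hidden_channels)
        w = lambda: rng.uniform(-limit, limit, size=shape)
        z = lambda: np.zeros(hidden_channels)
        return cls(
            w_i=w(), w_f=w(), w_c=w(), w_o=w(),
            b_i=z(), b_f=z() + forget_bias, b_c=z(), b_o=z(),
        )

    def fused(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack the four gates into one kernel/bias (order i, f, c, o)."""
        w = np.concatenate([self.w_i, self.w_f, self.w_c, self.w_o], axis=-1)
        b = np.concatenate([self.b_i, self.b_f, self.b_c, self.b_o])
        return w, b

    @classmethod
    def from_fused(cls, w: np.ndarray, b: np.ndarray) -> "ConvLSTMParams":
        n = w.shape[-1] // 4
        wi, wf, wc, wo = (w[..., i * n : (i + 1) * n] for i in range(4))
        bi, bf, bc, bo = (b[i * n : (i + 1) * n] for i in range(4))
        return cls(w_i=wi, w_f=wf, w_c=wc, w_o=wo, b_i=bi, b_f=bf, b_c=bc, b_o=bo)


@dataclass
class CellState:
    """Recurrent state: hidden map ``h`` and cell map ``c``, both (H, W, hidden)."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.c.shape:
            raise ValueError(f"h shape {self.h.shape} != c shape {self.c.shape}")

    @classmethod
    def zeros(cls, height: int, width: int, hidden_channels: int) -> "CellState":
        return cls(
            h=np.zeros((height, width, hidden_channels)),
            c=np.zeros((height, width, hidden_channels)),
        )


def _concat(x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    if x_t.shape[:2] != h_prev.shape[:2]:
        raise ValueError(
            f"input {x_t.shape[:2]} and hidden state {h_prev.shape[:2]} "
            "are not spatially aligned"
        )
    return np.concatenate([h_prev, x_t], axis=-1)


def _gate(x_t, h_prev, w, b):
    a = _concat(x_t, h_prev)
    return sigmoid(conv_forward(a[None], w, b)[0])


def gate_forget(x_t: np.ndarray, h_prev: np.ndarray, params: ConvLSTMParams) -> np.ndarray:
    """Forget gate f_t = sigmoid(w_f * [h_{t-1}, x_t] + b_f), values in (0, 1)."""
    return _gate(x_t, h_prev, params.w_f, params.b_f)


def gate_input(x_t: np.ndarray, h_prev: np.ndarray, params: ConvLSTMParams) -> np.ndarray:
    """Input gate i_t = sigmoid(w_i * [h_{t-1}, x_t] + b_i)."""
    return _gate(x_t, h_prev, params.w_i, params.b_i)


def gate_output(x_t: np.ndarray, h_prev: np.ndarray, params: ConvLSTMParams) -> np.ndarray:
    """Output gate o_t = sigmoid(w_o * [h_{t-1}, x_t] + b_o)."""
    return _gate(x_t, h_prev, params.w_o, params.b_o)


def cell_step(
    x_t: np.ndarray,
    state_prev: CellState,
    params: ConvLSTMParams,
    candidate_activation: str = "tanh",
    output_activation: str = "relu",
) -> CellState:
    """One recurrence step: gate the previous cell map and emit h_t.

    ``x_t`` is an (H, W, C_in) frame.  Returns the next :class:`CellState`.
    """
    f_t = gate_forget(x_t, state_prev.h, params)
    i_t = gate_input(x_t, state_prev.h, params)
    o_t = gate_output(x_t, state_prev.h, params)
    a = _concat(x_t, state_prev.h)
    g_t = _activation(candidate_activation)(
        conv_forward(a[None], params.w_c, params.b_c)[0]
    )
    c_t = f_t * state_prev.c + i_t * g_t
    h_t = o_t * _activation(output_activation)(c_t)
    return CellState(h=h_t, c=c_t)


def sequence_forward(
    frames: np.ndarray,
    params: ConvLSTMParams,
    return_sequence: bool = True,
    candidate_activation: str = "tanh",
    output_activation: str = "relu",
) -> np.ndarray:
    """Run the cell over a (T, H, W, C_in) stack from a zero state.

    Returns the (T, H, W, hidden) stack of hidden maps, or only the final
    hidden map when ``return_sequence`` is false.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty (T, H, W, C) stack")
    state = CellState.zeros(frames.shape[1], frames.shape[2], params.hidden_channels)
    hs = []
    for t in range(frames.shape[0]):
        state = cell_step(
            frames[t], state, params,
            candidate_activation=candidate_activation,
            output_activation=output_activation,
        )
        hs.append(state.h)
    return np.stack(hs) if return_sequence else state.h
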