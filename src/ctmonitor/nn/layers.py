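"""Trainable layers with explicit forward/backward passes.

Every layer owns its parameters and the gradients of the most recent
backward pass; :class:`ctmonitor.nn.model.Model` wires layers together and
drives the optimizer.  Shapes exclude the batch axis unless stated.
"""

from __future__ import annotations

import numpy as np

from .conv import conv_backward, conv_forward


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out

__all__ = [
    "Layer",
    "Conv",
    "ConvLSTM2D",
    "MaxPool",
    "GlobalAveragePool",
    "BatchNorm",
    "Dense",
    "Flatten",
    "Dropout",
]


# ---------------------------------------------------------------- activations

def act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return sigmoid(z)
    if name == "tanh":
        return np.tanh(z)
    if name == "softmax":
        e = np.exp(z - z.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation {name!r}")


def act_backward(name: str, z: np.ndarray, a: np.ndarray, da: np.ndarray) -> np.ndarray:
    if name == "linear":
        return da
    if name == "relu":
        return da * (z > 0)
    if name == "sigmoid":
        return da * a * (1.0 - a)
    if name == "tanh":
        return da * (1.0 - a * a)
    if name == "softmax":
        return a * (da - (da * a).sum(axis=-1, keepdims=True))
    raise ValueError(f"unknown activation {name!r}")


def _from_output_backward(name: str, a: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Activation backward expressed through the output value only."""
    if name == "linear":
        return da
    if name == "relu":
        return da * (a > 0)
    if name == "tanh":
        return da * (1.0 - a * a)
    if name == "sigmoid":
        return da * a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: subclasses set ``self.params``/``self.grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        return input_shape

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv(Layer):
    """Stride-1 "same" convolution over ``ndim`` spatial axes, fused activation.

    With ``ndim=3`` and a (T, H, W, C) input this is the spatio-temporal
    convolution used as the frame predictor's output head.
    """

    def __init__(self, filters: int, kernel_size: int | tuple[int, ...],
                 ndim: int, activation: str = "linear") -> None:
        super().__init__()
        self.filters = filters
        self.kernel_size = (kernel_size,) * ndim if np.isscalar(kernel_size) else tuple(kernel_size)
        self.ndim = ndim
        self.activation = activation

    def build(self, input_shape, rng):
        if len(input_shape) != self.ndim + 1:
            raise ValueError(f"Conv(ndim={self.ndim}) expects rank-{self.ndim + 1} inputs")
        c_in = input_shape[-1]
        k = int(np.prod(self.kernel_size))
        self.params["w"] = _glorot(
            rng, self.kernel_size + (c_in, self.filters), k * c_in, k * self.filters
        )
        self.params["b"] = np.zeros(self.filters)
        return input_shape[:-1] + (self.filters,)

    def forward(self, x, training=False):
        self._x = x
        self._z = conv_forward(x, self.params["w"], self.params["b"])
        self._a = act_forward(self.activation, self._z)
        return self._a

    def backward(self, dy):
        dz = act_backward(self.activation, self._z, self._a, dy)
        dx, dw, db = conv_backward(self._x, self.params["w"], dz)
        self.grads["w"], self.grads["b"] = dw, db
        return dx


class ConvLSTM2D(Layer):
    """Convolutional LSTM over (N, T, H, W, C) stacks, trained with BPTT.

    The four gate kernels are stored fused (order i, f, c, o) over the
    concatenation [h_{t-1}, x_t]; :meth:`to_core_params` exposes them as
    per-gate :class:`~ctmonitor.convlstm_core.ConvLSTMParams`.
    """

    def __init__(self, filters: int, kernel_size: int, return_sequences: bool = True,
                 candidate_activation: str = "tanh", output_activation: str = "relu") -> None:
        super().__init__()
        self.filters = filters
        self.kernel_size = kernel_size
        self.return_sequences = return_sequences
        self.candidate_activation = candidate_activation
        self.output_activation = output_activation

    def build(self, input_shape, rng):
        from ..convlstm_core import ConvLSTMParams

        t, h, w, c = input_shape
        core = ConvLSTMParams.init(rng, self.kernel_size, c, self.filters)
        self.params["w"], self.params["b"] = core.fused()
        self._in_channels = c
        if self.return_sequences:
            return (t, h, w, self.filters)
        return (h, w, self.filters)

    def to_core_params(self):
        """Expose the fused kernel as per-gate ConvLSTMParams."""
        from ..convlstm_core import ConvLSTMParams

        return ConvLSTMParams.from_fused(self.params["w"], self.params["b"])

    def forward(self, x, training=False):
        n, t, hh, ww, _ = x.shape
        f = self.filters
        h = np.zeros((n, hh, ww, f))
        c = np.zeros((n, hh, ww, f))
        self._cache = []
        self._x_shape = x.shape
        hs = np.empty((n, t, hh, ww, f))
        for step in range(t):
            a = np.concatenate([h, x[:, step]], axis=-1)
            z = conv_forward(a, self.params["w"], self.params["b"])
            i = sigmoid(z[..., :f])
            fg = sigmoid(z[..., f : 2 * f])
            g = act_forward(self.candidate_activation, z[..., 2 * f : 3 * f])
            o = sigmoid(z[..., 3 * f :])
            c_prev = c
            c = fg * c_prev + i * g
            ac = act_forward(self.output_activation, c)
            h = o * ac
            self._cache.append((a, i, fg, g, o, c_prev, c, ac))
            hs[:, step] = h
        return hs if self.return_sequences else h

    def backward(self, dy):
        n, t, hh, ww, _ = self._x_shape
        f = self.filters
        dw = np.zeros_like(self.params["w"])
        db = np.zeros_like(self.params["b"])
        dx = np.empty(self._x_shape)
        dh_next = np.zeros((n, hh, ww, f))
        dc_next = np.zeros((n, hh, ww, f))
        for step in range(t - 1, -1, -1):
            a, i, fg, g, o, c_prev, c, ac = self._cache[step]
            if self.return_sequences:
                dh = dy[:, step] + dh_next
            else:
                dh = (dy if step == t - 1 else 0.0) + dh_next
            do = dh * ac
            dc = dc_next + act_backward(self.output_activation, c, ac, dh * o)
            dfg = dc * c_prev
            dc_next = dc * fg
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    dfg * fg * (1.0 - fg),
                    _from_output_backward(self.candidate_activation, g, dg),
                    do * o * (1.0 - o),
                ],
                axis=-1,
            )
            da, dw_t, db_t = conv_backward(a, self.params["w"], dz)
            dw += dw_t
            db += db_t
            dh_next = da[..., :f]
            dx[:, step] = da[..., f:]
        self.grads["w"], self.grads["b"] = dw, db
        self._cache = None
        return dx


class MaxPool(Layer):
    """Non-overlapping max pooling over ``ndim`` trailing spatial axes.

    Window equals stride; remainders that do not fill a window are cropped,
    so output dims are floor(in / window) per axis.
    """

    def __init__(self, window: int | tuple[int, ...], ndim: int) -> None:
        super().__init__()
        self.ndim = ndim
        self.window = (window,) * ndim if np.isscalar(window) else tuple(window)

    def build(self, input_shape, rng):
        spatial = input_shape[:-1]
        if len(spatial) != self.ndim:
            raise ValueError(f"MaxPool(ndim={self.ndim}) expects rank-{self.ndim + 1} inputs")
        if any(d < k for d, k in zip(spatial, self.window)):
            raise ValueError(
                f"pooling window {self.window} does not fit input {spatial}; "
                f"each axis must be at least {self.window}"
            )
        out = tuple(d // k for d, k in zip(spatial, self.window))
        return out + (input_shape[-1],)

    def _split(self, x):
        n = x.shape[0]
        spatial = x.shape[1:-1]
        c = x.shape[-1]
        out = [d // k for d, k in zip(spatial, self.window)]
        crop = (slice(None),) + tuple(slice(0, o * k) for o, k in zip(out, self.window)) + (slice(None),)
        xc = x[crop]
        shape = [n] + [v for o, k in zip(out, self.window) for v in (o, k)] + [c]
        xr = xc.reshape(shape)
        s = self.ndim
        perm = [0] + [1 + 2 * i for i in range(s)] + [1 + 2 * s] + [2 + 2 * i for i in range(s)]
        xt = xr.transpose(perm)
        flat = xt.reshape((n, *out, c, int(np.prod(self.window))))
        return flat, out, c

    def forward(self, x, training=False):
        self._x_shape = x.shape
        flat, out, c = self._split(x)
        self._arg = flat.argmax(axis=-1)
        self._out = out
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n = self._x_shape[0]
        c = self._x_shape[-1]
        out = self._out
        kprod = int(np.prod(self.window))
        dflat = np.zeros((n, *out, c, kprod))
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        s = self.ndim
        # invert the transpose/reshape of _split
        xt_shape = (n, *out, c, *self.window)
        dxt = dflat.reshape(xt_shape)
        perm = [0] + [1 + 2 * i for i in range(s)] + [1 + 2 * s] + [2 + 2 * i for i in range(s)]
        inv = np.argsort(perm)
        dxr = dxt.transpose(inv)
        cropped = dxr.reshape((n, *[o * k for o, k in zip(out, self.window)], c))
        dx = np.zeros(self._x_shape)
        sl = (slice(None),) + tuple(slice(0, d) for d in cropped.shape[1:-1]) + (slice(None),)
        dx[sl] = cropped
        return dx


class GlobalAveragePool(Layer):
    """Channel-wise mean over all spatial axes: (N, *spatial, C) -> (N, C)."""

    def build(self, input_shape, rng):
        self._spatial = input_shape[:-1]
        return (input_shape[-1],)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, dy):
        m = int(np.prod(self._shape[1:-1]))
        shape = (self._shape[0],) + (1,) * (len(self._shape) - 2) + (self._shape[-1],)
        return np.broadcast_to(dy.reshape(shape) / m, self._shape).copy()


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        return input_shape

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._m = int(np.prod([x.shape[i] for i in axes]))
            self._xc = x - mu
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = self._xc * self._istd
            return self.params["gamma"] * self._xhat + self.params["beta"]
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        m = self._m
        dvar = (dxhat * self._xc).sum(axis=axes) * (-0.5) * self._istd**3
        dmu = -(dxhat.sum(axis=axes)) * self._istd + dvar * (-2.0 / m) * self._xc.sum(axis=axes)
        dx = dxhat * self._istd + dvar * 2.0 * self._xc / m + dmu / m
        self._xc = self._xhat = None
        return dx


class Dense(Layer):
    def __init__(self, units: int, activation: str = "linear") -> None:
        super().__init__()
        self.units = units
        self.activation = activation

    def build(self, input_shape, rng):
        (d,) = input_shape
        self.params["w"] = _glorot(rng, (d, self.units), d, self.units)
        self.params["b"] = np.zeros(self.units)
        return (self.units,)

    def forward(self, x, training=False):
        self._x = x
        self._z = x @ self.params["w"] + self.params["b"]
        self._a = act_forward(self.activation, self._z)
        return self._a

    def backward(self, dy):
        dz = act_backward(self.activation, self._z, self._a, dy)
        self.grads["w"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["w"].T


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dy):
        return dy.reshape((self._n, *self._shape))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def build(self, input_shape, rng):
        self._rng = np.random.default_rng(rng.integers(2**31))
        return input_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask
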