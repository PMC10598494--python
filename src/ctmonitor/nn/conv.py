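"""N-dimensional "same"-padded, stride-1 cross-correlation with exact gradients.

Convolutions are evaluated as a sum of shifted matrix products (one
tensordot per kernel offset), which keeps memory at O(input) and routes
the arithmetic through BLAS.  The same primitive serves 2-D feature maps,
3-D volumes and the spatio-temporal kernel of the frame predictor: the
number of spatial axes is inferred from the kernel rank.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["conv_forward", "conv_backward"]


def _pad_widths(kernel_shape: tuple[int, ...]) -> list[tuple[int, int]]:
    # "same" for stride 1: total pad k-1, extra on the trailing side for even k
    return [((k - 1) // 2, k // 2) for k in kernel_shape]


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Cross-correlate ``x`` with ``w``.

    Parameters
    ----------
    x : (N, *spatial, C_in) array
    w : (*kernel, C_in, C_out) array; ``len(kernel)`` spatial axes
    b : (C_out,) array, optional

    Returns
    -------
    (N, *spatial, C_out) array (zero-padded "same" output, stride 1).
    """
    s = w.ndim - 2
    if x.ndim != s + 2:
        raise ValueError(f"input rank {x.ndim} incompatible with kernel rank {w.ndim}")
    if x.shape[-1] != w.shape[-2]:
        raise ValueError(f"input has {x.shape[-1]} channels, kernel expects {w.shape[-2]}")
    kernel = w.shape[:s]
    spatial = x.shape[1:-1]
    xp = np.pad(x, [(0, 0)] + _pad_widths(kernel) + [(0, 0)])
    y = np.zeros(x.shape[:1] + spatial + (w.shape[-1],), dtype=np.result_type(x, w))
    for idx in itertools.product(*(range(k) for k in kernel)):
        sl = (slice(None),) + tuple(slice(i, i + n) for i, n in zip(idx, spatial))
        y += np.tensordot(xp[sl], w[idx], axes=([-1], [0]))
    if b is not None:
        y += b
    return y


def conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_forward` w.r.t. input, kernel and bias.

    Returns ``(dx, dw, db)`` with the same shapes as ``x``, ``w`` and the
    bias.  ``dy`` is the upstream gradient, shaped like the forward output.
    """
    s = w.ndim - 2
    kernel = w.shape[:s]
    spatial = x.shape[1:-1]
    pads = _pad_widths(kernel)
    xp = np.pad(x, [(0, 0)] + pads + [(0, 0)])
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    sum_axes = list(range(s + 1))  # batch + spatial axes
    for idx in itertools.product(*(range(k) for k in kernel)):
        sl = (slice(None),) + tuple(slice(i, i + n) for i, n in zip(idx, spatial))
        dw[idx] = np.tensordot(xp[sl], dy, axes=(sum_axes, sum_axes))
        dxp[sl] += np.tensordot(dy, w[idx], axes=([-1], [1]))
    db = dy.sum(axis=tuple(sum_axes))
    unpad = (slice(None),) + tuple(
        slice(lo, lo + n) for (lo, _), n in zip(pads, spatial)
    ) + (slice(None),)
    return dxp[unpad], dw, db
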