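"""NumPy primitives for the temporal convolutional classifier.

The convolution is a *true* discrete convolution (kernel flipped), evaluated
in "valid" mode along time with the channel/filter axis acting as depth:

    y[o, j] = sum_c sum_m x[c, j + m] * w[o, c, k - 1 - m]

which for each output filter equals ``sum_c np.convolve(x[c], w[o, c],
'valid')``.  Output length is ``L - k + 1``.  Average pooling halves the
temporal extent (non-overlapping pairs, odd trailing element dropped).  All
layers carry hand-derived adjoints so the network trains without an autodiff
framework; gradients are verified against finite differences in the tests.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "conv1d_adjoint_input",
    "relu",
    "avg_pool",
    "avg_pool_backward",
    "avg_unpool",
    "softmax",
    "cross_entropy",
    "Adam",
]


def _as_batch(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ValueError(f"expected 2-D or 3-D input, got shape {x.shape}")


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Valid temporal convolution with kernel flip (true convolution).

    x: (C_in, L) or (N, C_in, L); w: (C_out, C_in, k); b: (C_out,) or None.
    Returns (N, C_out, L - k + 1) (batch axis squeezed if input was 2-D).
    """
    xb, squeeze = _as_batch(np.asarray(x, dtype=np.float64))
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[-1]
    L = xb.shape[-1]
    if k > L:
        raise ValueError(f"kernel size {k} exceeds input temporal extent {L}")
    if xb.shape[1] != w.shape[1]:
        raise ValueError(
            f"input has {xb.shape[1]} channels but kernels expect {w.shape[1]}"
        )
    win = sliding_window_view(xb, k, axis=-1)  # (N, C_in, L-k+1, k)
    out = np.einsum("nclk,ock->nol", win, w[:, :, ::-1], optimize=True)
    if b is not None:
        out = out + np.asarray(b, dtype=np.float64)[None, :, None]
    return out[0] if squeeze else out


def conv1d_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a scalar loss through conv1d_forward.

    x: (N, C_in, L); w: (C_out, C_in, k); dy: (N, C_out, L_out).
    Returns (dx, dw, db).
    """
    k = w.shape[-1]
    win = sliding_window_view(x, k, axis=-1)
    dw_flipped = np.einsum("nclk,nol->ock", win, dy, optimize=True)
    dw = dw_flipped[:, :, ::-1]
    db = dy.sum(axis=(0, 2))
    dx = conv1d_adjoint_input(dy, w)
    return dx, dw, db


def conv1d_adjoint_input(dy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Adjoint of conv1d_forward w.r.t. its input (a transposed convolution).

    Maps (N, C_out, L_out) back to (N, C_in, L_out + k - 1); also the
    back-projection step of the deconvolution visualizer.
    """
    dyb, squeeze = _as_batch(np.asarray(dy, dtype=np.float64))
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[-1]
    pad = np.pad(dyb, ((0, 0), (0, 0), (k - 1, k - 1)))
    win = sliding_window_view(pad, k, axis=-1)  # (N, C_out, L_in, k)
    # y[o, j] used x[c, j + m] * w[o, c, k-1-m]  =>  x'[c, t] = sum_{o,m} dy[o, t - m] w[o, c, k-1-m]
    dx = np.einsum("nolk,ock->ncl", win, w, optimize=True)
    return dx[0] if squeeze else dx


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def avg_pool(x: np.ndarray, kernel: int = 2) -> np.ndarray:
    """Average pooling over non-overlapping windows along time (stride = kernel).

    An odd trailing element is dropped; output length = floor(L / kernel).
    """
    L = x.shape[-1]
    if L < kernel:
        raise ValueError(f"cannot pool temporal extent {L} with kernel {kernel}")
    L_out = L // kernel
    trimmed = x[..., : L_out * kernel]
    return trimmed.reshape(*x.shape[:-1], L_out, kernel).mean(axis=-1)


def avg_pool_backward(dy: np.ndarray, input_length: int, kernel: int = 2) -> np.ndarray:
    """Gradient of avg_pool: each pooled gradient spread as dy/kernel."""
    dx = np.zeros((*dy.shape[:-1], input_length), dtype=np.float64)
    L_out = dy.shape[-1]
    spread = np.repeat(dy / kernel, kernel, axis=-1)
    dx[..., : L_out * kernel] = spread
    return dx


def avg_unpool(a: np.ndarray, output_length: int, kernel: int = 2) -> np.ndarray:
    """Reverse average pooling by uniform redistribution (the pooling adjoint).

    Each pooled value is split equally across its pool window; positions
    beyond ``kernel * L_pool`` (an odd trailing element dropped on the forward
    pass) receive zero.
    """
    return avg_pool_backward(a, output_length, kernel)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax: invariant to adding a constant to all logits."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under probs (N, K)."""
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
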