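"""Minimal differentiable numpy backend for small 1D convolutional nets.

Implements exactly the layer set the balance-control models need — 1D
same-padded convolution, Leaky ReLU, non-overlapping max pooling, dense
layers, inverted dropout, residual blocks and a softmax cross-entropy
head — each with a hand-written backward pass, plus the Adam optimizer.

Shapes: convolutional layers operate on ``[batch, length, channels]``
arrays (length-major, so im2col windows reshape without transposing);
dense layers on ``[batch, features]``. Forward passes cache what their
backward pass needs; call ``backward`` at most once per ``forward``.
Dropout is active only when a ``rng`` is passed to ``forward`` (training
mode); with ``rng=None`` every layer is deterministic.

Convolutions are evaluated as a single GEMM over a strided window view of
the padded input, and the input gradient as the flipped-kernel GEMM of
the padded output gradient; the optimizer folds every parameter into one
flat master vector so an update is a handful of whole-vector operations
regardless of layer count. Parameters default to single precision
(``DTYPE``); pass ``dtype=np.float64`` when building layers for
finite-difference work.

The forward semantics of each layer are validated against the pure oracle
functions in :mod:`copnet.net_core`; gradients are validated by central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False

__all__ = [
    "DTYPE",
    "Param",
    "Layer",
    "Conv1dSame",
    "LeakyReLU",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "ResidualBlock",
    "ParallelConcat",
    "SoftmaxCrossEntropy",
    "Adam",
]

DTYPE = np.float32


class Param:
    """A trainable array with its gradient.

    ``value`` and ``grad`` may be rebound to views into an optimizer's
    flat master buffers; layers therefore write gradients in place
    (``p.grad[...] = ...``) and read ``p.value`` afresh on every forward.
    """

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def _window_cols(xp: np.ndarray, L: int, k: int) -> np.ndarray:
    """im2col for [B, Lp, C]: returns a [B*L, C*k] copy, window order (c, j)."""
    B, Lp, C = xp.shape
    s0, s1, s2 = xp.strides
    win = as_strided(xp, shape=(B, L, C, k), strides=(s0, s1, s2, s1))
    return win.reshape(B * L, C * k)


class Conv1dSame(Layer):
    """Same-padded 1D cross-correlation: output length equals input length.

    Padding is asymmetric for even kernels — ``floor((k-1)/2)`` zeros on
    the left and ``ceil((k-1)/2)`` on the right. Weights are stored as
    ``[c_out, c_in, k]``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        dtype=DTYPE,
        activation_slope: float | None = None,
    ):
        if min(c_in, c_out, kernel_size) < 1:
            raise ValueError("channel counts and kernel size must be >= 1")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        fan_in = c_in * kernel_size
        self.W = Param(_fan_in_uniform(rng, (c_out, c_in, kernel_size), fan_in, dtype))
        self.b = Param(_fan_in_uniform(rng, (c_out,), fan_in, dtype))
        self._pad_left = (kernel_size - 1) // 2
        self._pad_right = kernel_size - 1 - self._pad_left
        self.activation_slope = activation_slope
        self._xp = self._dyp = None  # reused padding buffers

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _padded(self, buf_attr: str, x: np.ndarray, left: int, right: int) -> np.ndarray:
        if left == 0 and right == 0:
            return x
        B, L, C = x.shape
        shape = (B, L + left + right, C)
        buf = getattr(self, buf_attr)
        if buf is None or buf.shape != shape or buf.dtype != x.dtype:
            buf = np.zeros(shape, dtype=x.dtype)  # pad regions stay zero
            setattr(self, buf_attr, buf)
        buf[:, left : left + L] = x
        return buf

    def forward(self, x, rng=None):
        if x.ndim != 3 or x.shape[2] != self.c_in:
            raise ValueError(
                f"expected [batch, length, {self.c_in}], got {x.shape}"
            )
        B, L, _ = x.shape
        xp = self._padded("_xp", x, self._pad_left, self._pad_right)
        cols = _window_cols(xp, L, self.k)
        W2 = self.W.value.reshape(self.c_out, -1)
        y = cols @ W2.T
        y += self.b.value
        self._cache = (cols, B, L)
        if self.activation_slope is not None:
            self._neg = y < 0
            y = np.where(self._neg, y * y.dtype.type(self.activation_slope), y)
        return y.reshape(B, L, self.c_out)

    def backward(self, dy):
        cols, B, L = self._cache
        dy2 = dy.reshape(B * L, self.c_out)
        if self.activation_slope is not None:
            dy2 = np.where(
                self._neg, dy2 * dy2.dtype.type(self.activation_slope), dy2
            )
        self.W.grad[...] = (dy2.T @ cols).reshape(self.W.value.shape)
        self.b.grad[...] = dy2.sum(axis=0)
        # dx[n] = sum_{co,j} dy[n + pad_left - j] * W[co, ci, j]:
        # a correlation of the re-padded dy with the flipped kernel
        dyp = self._padded(
            "_dyp", dy2.reshape(B, L, self.c_out),
            self.k - 1 - self._pad_left, self._pad_left,
        )
        dcols = _window_cols(dyp, L, self.k)
        Wflip = np.ascontiguousarray(
            self.W.value[:, :, ::-1].transpose(1, 0, 2)
        ).reshape(self.c_in, -1)
        dx = dcols @ Wflip.T
        return dx.reshape(B, L, self.c_in)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        if not 0 < slope < 1:
            raise ValueError("slope must lie in (0, 1)")
        self.slope = slope

    def forward(self, x, rng=None):
        # for 0 < slope < 1, max(x, slope*x) IS the leaky rectifier
        self._neg = x < 0
        return np.maximum(x, x * x.dtype.type(self.slope))

    def backward(self, dy):
        return np.where(self._neg, dy * dy.dtype.type(self.slope), dy)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; the trailing remainder is dropped."""

    def __init__(self, p: int):
        if p < 1:
            raise ValueError("pool size must be >= 1")
        self.p = p

    def forward(self, x, rng=None):
        B, L, C = x.shape
        s = L // self.p
        if s == 0:
            raise ValueError(f"cannot pool length {L} with p={self.p}")
        blocks = x[:, : s * self.p].reshape(B, s, self.p, C)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def _base_index(self, B: int, s: int, C: int) -> np.ndarray:
        # flat index of (b, s_i, 0, c) within the cropped [B, s*p, C]
        cached = getattr(self, "_base", None)
        if cached is not None and cached.shape == (B, s, C):
            return cached
        self._base = (
            np.arange(B * s).reshape(B, s, 1) * (self.p * C)
            + np.arange(C).reshape(1, 1, C)
        )
        return self._base

    def backward(self, dy):
        B, L, C = self._in_shape
        s = L // self.p
        base = self._base_index(B, s, C)
        cropped = np.zeros(B * s * self.p * C, dtype=dy.dtype)
        cropped[(base + self._argmax * C).ravel()] = dy.ravel()
        if s * self.p == L:
            return cropped.reshape(B, L, C)
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        dx[:, : s * self.p] = cropped.reshape(B, s * self.p, C)
        return dx


class Flatten(Layer):
    def forward(self, x, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        dtype=DTYPE,
        activation_slope: float | None = None,
    ):
        self.n_in, self.n_out = n_in, n_out
        self.W = Param(_fan_in_uniform(rng, (n_in, n_out), n_in, dtype))
        self.b = Param(_fan_in_uniform(rng, (n_out,), n_in, dtype))
        self.activation_slope = activation_slope

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, rng=None):
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"expected [batch, {self.n_in}], got {x.shape}")
        self._x = x
        y = x @ self.W.value + self.b.value
        if self.activation_slope is not None:
            self._neg = y < 0
            y = np.where(self._neg, y * y.dtype.type(self.activation_slope), y)
        return y

    def backward(self, dy):
        if self.activation_slope is not None:
            dy = np.where(self._neg, dy * dy.dtype.type(self.activation_slope), dy)
        self.W.grad[...] = self._x.T @ dy
        self.b.grad[...] = dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout; identity when no rng is supplied (eval mode)."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, rng=None):
        if rng is None or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype)
        self._mask /= x.dtype.type(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, rng=None):
        for layer in self.layers:
            x = layer.forward(x, rng)
        return x

    def forward_upto(self, x, n_layers: int, rng=None):
        """Forward pass through the first ``n_layers`` layers only."""
        for layer in self.layers[:n_layers]:
            x = layer.forward(x, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Short-cut sum ``act(main(x) + shortcut(x))`` (post-sum activation).

    ``shortcut`` is the identity when input and output channel counts
    match, otherwise a 1x1 convolution projecting the input.
    """

    def __init__(self, main: Sequential, shortcut: Layer | None, slope: float = 0.01):
        self.main = main
        self.shortcut = shortcut
        self.act = LeakyReLU(slope)

    def params(self) -> list[Param]:
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, rng=None):
        r = self.main.forward(x, rng)
        s = x if self.shortcut is None else self.shortcut.forward(x, rng)
        if r.shape != s.shape:
            raise ValueError(
                f"residual branch shape {r.shape} does not match shortcut {s.shape}"
            )
        return self.act.forward(r + s, rng)

    def backward(self, dy):
        dsum = self.act.backward(dy)
        dx = self.main.backward(dsum)
        if self.shortcut is None:
            dx = dx + dsum
        else:
            dx = dx + self.shortcut.backward(dsum)
        return dx


class ParallelConcat(Layer):
    """Run branches on the same input; concatenate their flat outputs."""

    def __init__(self, branches: Sequence[Sequential]):
        if not branches:
            raise ValueError("need at least one branch")
        self.branches = list(branches)

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, rng=None):
        outs = [b.forward(x, rng) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(dy, splits, axis=1)
        dx = self.branches[0].backward(np.ascontiguousarray(parts[0]))
        for b, part in zip(self.branches[1:], parts[1:]):
            dx = dx + b.backward(np.ascontiguousarray(part))
        return dx


class SoftmaxCrossEntropy:
    """Fused softmax + mean cross-entropy head with its analytic gradient."""

    def probs(self, logits: np.ndarray) -> np.ndarray:
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
        """Return (mean loss, dloss/dlogits)."""
        p = self.probs(logits)
        n = logits.shape[0]
        picked = np.clip(p[np.arange(n), labels], 1e-12, 1.0)
        loss = float(-np.log(picked.astype(np.float64)).mean())
        dlogits = p.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= dlogits.dtype.type(n)
        return loss, dlogits


if _HAVE_NUMBA:

    # all scalars arrive pre-cast to the parameter dtype so the loop body
    # stays single-precision end to end (and SIMD-vectorizes)
    @_njit(fastmath=True, cache=False)
    def _adam_kernel(values, grads, m, v, b1, b1c, b2, b2c, lr_t, eps_t):  # pragma: no cover
        for i in range(values.size):
            g = grads[i]
            m[i] = b1 * m[i] + b1c * g
            v[i] = b2 * v[i] + b2c * g * g
            values[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps_t)


class Adam:
    """Adam optimizer with the conventional defaults (b1=0.9, b2=0.999).

    On construction, all parameter values and gradients are repacked into
    flat master vectors (the ``Param`` objects become views into them), so
    one step is a single fused pass over the parameters (numba) or a
    handful of whole-vector in-place operations (numpy fallback). The
    bias-corrected update ``lr * m_hat / (sqrt(v_hat) + eps)`` is applied
    in the algebraically identical single-scaling form
    ``lr_t * m / (sqrt(v) + eps_t)`` with ``lr_t = lr * sqrt(1 - b2^t) /
    (1 - b1^t)`` and ``eps_t = eps * sqrt(1 - b2^t)``.
    """

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        sizes = [p.value.size for p in self.params]
        total = int(sum(sizes))
        dtype = self.params[0].value.dtype if self.params else DTYPE
        self.values = np.empty(total, dtype=dtype)
        self.grads = np.zeros(total, dtype=dtype)
        offset = 0
        for p in self.params:
            n = p.value.size
            self.values[offset : offset + n] = p.value.ravel()
            p.value = self.values[offset : offset + n].reshape(p.value.shape)
            p.grad = self.grads[offset : offset + n].reshape(p.grad.shape)
            offset += n
        self.m = np.zeros(total, dtype=dtype)
        self.v = np.zeros(total, dtype=dtype)
        self._buf = np.empty(total, dtype=dtype)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias2_sqrt = np.sqrt(1.0 - b2**self.t)
        lr_t = self.lr * bias2_sqrt / (1.0 - b1**self.t)
        eps_t = self.eps * bias2_sqrt
        if _HAVE_NUMBA:
            dt = self.values.dtype.type
            _adam_kernel(
                self.values, self.grads, self.m, self.v,
                dt(b1), dt(1.0 - b1), dt(b2), dt(1.0 - b2), dt(lr_t), dt(eps_t),
            )
            return
        g, buf = self.grads, self._buf
        self.m *= b1
        self.m += (1.0 - b1) * g
        np.square(g, out=buf)
        self.v *= b2
        self.v += (1.0 - b2) * buf
        np.sqrt(self.v, out=buf)
        buf += eps_t
        np.divide(self.m, buf, out=buf)
        buf *= lr_t
        self.values -= buf
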