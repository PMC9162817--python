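"""Reference implementations of the elementary network computations.

Pure, deterministic numpy functions for 1D convolution, pooling, the Leaky
ReLU activation, softmax, cross-entropy and the residual (short-cut) sum.
These serve as the forward-pass oracle against which the trainable backend
in :mod:`copnet.backend` is validated; no gradients are defined here.

Conventions
-----------
* Convolution uses the cross-correlation convention (no kernel flip):
  ``k_i = eta(w . x[i:i+F_L] + m)``.
* Indexing is 0-based with half-open windows.
* "Same" padding is asymmetric for even kernels: ``floor((F_L-1)/2)`` zeros
  on the left, ``ceil((F_L-1)/2)`` on the right, so output length equals
  input length.
* Max pooling uses non-overlapping blocks; a trailing remainder shorter
  than the pool size is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConvFilter",
    "FeatureMap",
    "concat_window",
    "conv1d_valid",
    "conv1d_same",
    "maxpool1d",
    "leaky_relu",
    "softmax",
    "cross_entropy",
    "residual_forward",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ConvFilter:
    """A single 1D convolution filter: weights ``w``, bias ``m``, activation."""

    w: np.ndarray
    m: float = 0.0
    activation: str = "identity"  # "identity" | "leaky_relu"
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("filter weights must be a non-empty 1D vector")
        if not np.all(np.isfinite(w)) or not np.isfinite(self.m):
            raise ValueError("filter weights and bias must be finite")
        if self.activation not in ("identity", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "w", w)

    @property
    def size(self) -> int:
        return int(self.w.size)

    def apply_activation(self, v: np.ndarray) -> np.ndarray:
        if self.activation == "leaky_relu":
            return leaky_relu(v, self.leaky_slope)
        return v


@dataclass
class FeatureMap:
    """A learned feature sequence, tagged with the originating kernel size."""

    values: np.ndarray
    scale_tag: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x.values if isinstance(x, FeatureMap) else x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1D series")
    return arr


def concat_window(x: Sequence[float], i: int, f_l: int) -> np.ndarray:
    """Return the concatenation vector ``(x_i, ..., x_{i+f_l-1})``.

    Raises ``IndexError`` when the window exceeds the series bounds.
    """
    arr = _as_series(x)
    if f_l < 1:
        raise ValueError("window length must be >= 1")
    if i < 0 or i + f_l > arr.size:
        raise IndexError(
            f"window [{i}, {i + f_l}) exceeds series of length {arr.size}"
        )
    return arr[i : i + f_l].copy()


def conv1d_valid(x: Sequence[float], f: ConvFilter) -> FeatureMap:
    """Valid (unpadded) 1D cross-correlation with bias and activation.

    Output index ``i`` is ``eta(w . x[i:i+F_L] + m)`` for
    ``i = 0 .. N - F_L``; output length is ``N - F_L + 1``.
    """
    arr = _as_series(x)
    if arr.size < f.size:
        raise ValueError(
            f"series length {arr.size} shorter than filter length {f.size}"
        )
    # np.correlate implements exactly the no-flip dot-product convention
    raw = np.correlate(arr, f.w, mode="valid") + f.m
    return FeatureMap(f.apply_activation(raw), scale_tag=f.size)


def conv1d_same(x: Sequence[float], f: ConvFilter) -> FeatureMap:
    """Zero-padded 1D cross-correlation preserving the input length.

    Pads ``floor((F_L-1)/2)`` zeros left and ``ceil((F_L-1)/2)`` right, then
    applies :func:`conv1d_valid`; ``len(output) == len(input)``.
    """
    arr = _as_series(x)
    left = (f.size - 1) // 2
    right = f.size - 1 - left
    padded = np.pad(arr, (left, right))
    out = conv1d_valid(padded, f)
    assert len(out) == arr.size
    return out


def maxpool1d(k, p: int) -> FeatureMap:
    """Max pooling over non-overlapping blocks of size ``p``.

    The trailing remainder shorter than ``p`` is dropped, so the output has
    ``floor(len(k) / p)`` entries.
    """
    arr = _as_series(k)
    if p < 1:
        raise ValueError("pool size must be >= 1")
    if arr.size < p:
        raise IndexError(f"cannot pool length-{arr.size} map with p={p}")
    s = arr.size // p
    pooled = arr[: s * p].reshape(s, p).max(axis=1)
    tag = k.scale_tag if isinstance(k, FeatureMap) else None
    return FeatureMap(pooled, scale_tag=tag)


def leaky_relu(v, slope: float = 0.01) -> np.ndarray:
    """Elementwise ``v if v >= 0 else slope * v``."""
    if not 0 < slope < 1:
        raise ValueError("slope must lie in (0, 1)")
    arr = np.asarray(v, dtype=float)
    return np.where(arr >= 0, arr, slope * arr)


def softmax(z) -> np.ndarray:
    """Numerically stable softmax: positive outputs summing to one."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("softmax inputs must be finite")
    shifted = arr - arr.max()
    e = np.exp(shifted)
    return e / e.sum()


def cross_entropy(p, label: int) -> float:
    """Negative log-probability of the true class, ``-log(p[label])``.

    Probabilities are clipped to ``[1e-12, 1]`` before the log.
    """
    arr = np.asarray(p, dtype=float)
    if not 0 <= label < arr.size:
        raise IndexError(f"label {label} out of range for {arr.size} classes")
    return float(-np.log(np.clip(arr[label], _PROB_FLOOR, 1.0)))


def residual_forward(
    x, inner: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Short-cut sum ``inner(x) + x``; ``inner`` must preserve the shape."""
    arr = np.asarray(x, dtype=float)
    r = np.asarray(inner(arr), dtype=float)
    if r.shape != arr.shape:
        raise ValueError(
            f"residual branch changed shape {arr.shape} -> {r.shape}"
        )
    return r + arr
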