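"""Minimal CPU neural-network layers with explicit backpropagation.

Each layer exposes ``forward(x, training)`` and ``backward(dy)``;
parameters and their gradients live in the ``params`` / ``grads`` dicts.
All computation is float32 via im2col + BLAS matrix products, which keeps
single-core training of small U-Nets tractable. Correctness of every
backward pass is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "BilinearUp2d"]

_F = np.float32


class Layer:
    """Base class: parameter bookkeeping and the forward/backward protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0


class Conv2d(Layer):
    """Stride-1 'same' convolution (zero padding) with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize)
        ).astype(_F)
        self.params["b"] = np.zeros(out_ch, dtype=_F)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            view = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
            cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
            cols = np.ascontiguousarray(cols, dtype=_F)
        self._cache = (cols, (n, c, h, w)) if training else (None, (n, c, h, w))
        wmat = self.params["w"].reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.params["b"]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dy2 = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch), dtype=_F
        )
        self.grads["w"] += (dy2.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] += dy2.sum(axis=0)
        dcols = dy2 @ self.params["w"].reshape(self.out_ch, -1)
        if k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=_F)
        self.params["beta"] = np.zeros(ch, dtype=_F)
        self.grads["gamma"] = np.zeros(ch, dtype=_F)
        self.grads["beta"] = np.zeros(ch, dtype=_F)
        self.running_mean = np.zeros(ch, dtype=_F)
        self.running_var = np.ones(ch, dtype=_F)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(_F)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_F)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        if training:
            self._cache = (xhat, ivstd)
        out = self.params["gamma"][None, :, None, None] * xhat
        out += self.params["beta"][None, :, None, None]
        return out.astype(_F)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.params["gamma"][None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * ivstd[None, :, None, None]
        return dx.astype(_F)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; ties share the gradient equally."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        if training:
            mask = r == out[:, :, :, None, :, None]
            self._cache = (mask, (n, c, h, w))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, (n, c, h, w) = self._cache
        counts = mask.sum(axis=(3, 5))
        dr = mask * (dy / counts)[:, :, :, None, :, None]
        return dr.reshape(n, c, h, w).astype(_F)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation operator (align_corners=False)."""
    w = np.zeros((n_out, n_in), dtype=_F)
    for o in range(n_out):
        cpos = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(cpos))
        frac = cpos - i0
        lo = min(max(i0, 0), n_in - 1)
        hi = min(max(i0 + 1, 0), n_in - 1)
        w[o, lo] += 1.0 - frac
        w[o, hi] += frac
    return w


class BilinearUp2d(Layer):
    """x2 bilinear upsampling as a fixed linear operator per axis.

    The backward pass is the exact adjoint of the forward operator.
    """

    _matrices: dict[tuple[int, int], np.ndarray] = {}

    @classmethod
    def _matrix(cls, n_in: int, n_out: int) -> np.ndarray:
        key = (n_in, n_out, np.dtype(_F).name)
        if key not in cls._matrices:
            cls._matrices[key] = _interp_matrix(n_in, n_out)
        return cls._matrices[key]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        wh = self._matrix(h, 2 * h)
        ww = self._matrix(w, 2 * w)
        if training:
            self._shapes = (h, w)
        return np.matmul(np.matmul(wh, x), ww.T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shapes
        wh = self._matrix(h, 2 * h)
        ww = self._matrix(w, 2 * w)
        return np.matmul(np.matmul(wh.T, dy), ww).astype(_F)
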