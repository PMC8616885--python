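"""Minimal neural-network building blocks in numpy with manual backprop.

The learned correctors need only a small, fixed set of differentiable
operations (3x3 convolutions, ReLU, 2x2 max pooling, 2x2 transposed
convolutions, channel concatenation and an Adam optimizer), so they are
implemented here directly on numpy arrays in ``(batch, channel, row, col)``
layout.  Every layer caches what its backward pass needs; gradients are
checked against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "ConvTranspose2", "Adam"]


class Conv2D:
    """Stride-1 2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, pad: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None, zero_init: bool = False,
                 bias: bool = True):
        self.k = k
        self.pad = (k - 1) // 2 if pad is None else pad
        if zero_init:
            self.w = np.zeros((c_out, c_in, k, k))
        else:
            rng = rng or np.random.default_rng()
            fan_in = c_in * k * k
            self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out) if bias else None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self._patches = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        patches = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        self._patches = patches  # (n, c_in, H, W, k, k)
        out = np.einsum("nchwij,ocij->nohw", patches, self.w, optimize=True)
        if self.b is not None:
            out += self.b[None, :, None, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw += np.einsum("nchwij,nohw->ocij", self._patches, g, optimize=True)
        if self.b is not None:
            self.gb += g.sum(axis=(0, 2, 3))
        # full correlation of g with the kernel rotated by 180 degrees
        k, p = self.k, self.pad
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1 - p, k - 1 - p), (k - 1 - p, k - 1 - p)))
        gpatches = sliding_window_view(gp, (k, k), axis=(2, 3))
        w_rot = self.w[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", gpatches, w_rot, optimize=True)

    @property
    def params(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    params: List = []


class MaxPool2:
    """2x2 max pooling with stride 2 (input sizes must be even).

    Ties are broken toward the first element of the window so the backward
    pass routes each output gradient to exactly one input.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        gr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        return (
            gr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    params: List = []


class ConvTranspose2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * 4
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nchw,coij->nohwij", x, self.w, optimize=True)
        out = out.transpose(0, 1, 2, 4, 3, 5).reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, o, H, W = g.shape
        gr = g.reshape(n, o, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.gw += np.einsum("nchw,nohwij->coij", self._x, gr, optimize=True)
        self.gb += g.sum(axis=(0, 2, 3))
        return np.einsum("nohwij,coij->nchw", gr, self.w, optimize=True)

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Adam:
    """Adam optimizer over a list of ``(param, grad)`` array pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
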