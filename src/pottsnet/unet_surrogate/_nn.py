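"""Minimal convolutional-network engine for the periodic U-Net.

Everything runs on the torus: convolutions use circular padding, so every
layer commutes exactly with cyclic shifts (up to float reduction order).
Layers implement explicit ``forward``/``backward`` passes in float32 numpy;
the only container is the hand-wired U-Net in ``model.py``.
"""

from __future__ import annotations

from typing import List

import numpy as np

__all__ = ["Param", "Conv2d", "PReLU", "MaxPool2", "Upsample2", "Sigmoid", "Adam", "Sequential"]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _conv_circ(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Circular cross-correlation: x (N,C,H,W) with kernels w (O,C,kh,kw)."""
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)), mode="wrap")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.einsum("nchwij,ocij->nohw", win, w, optimize=True)


class Conv2d:
    """Same-size convolution with circular padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        fan_in = c_in * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel_size, kernel_size))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _conv_circ(x, self.w.value) + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._x, self.w.value
        kh, kw = w.shape[2], w.shape[3]
        xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)), mode="wrap")
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        self.w.grad += np.einsum("nchwij,nohw->ocij", win, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        # Gradient w.r.t. input: circular correlation with the transposed,
        # spatially flipped kernel (exact adjoint on the torus).
        w_adj = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        return _conv_circ(dy, np.ascontiguousarray(w_adj))

    def params(self) -> List[Param]:
        return [self.w, self.b]


class PReLU:
    """Parametric ReLU with one learnable slope per channel (init 0.25)."""

    def __init__(self, channels: int):
        self.alpha = Param(np.full(channels, 0.25))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = self.alpha.value[None, :, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = np.minimum(x, 0.0)
        self.alpha.grad += (dy * neg).sum(axis=(0, 2, 3))
        a = self.alpha.value[None, :, None, None]
        return np.where(x > 0, dy, a * dy)

    def params(self) -> List[Param]:
        return [self.alpha]


class MaxPool2:
    """2x2 max pooling, stride 2 (first-maximum tie-break)."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, h, w)

    def params(self) -> List[Param]:
        return []


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self) -> List[Param]:
        return []


class Sigmoid:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)

    def params(self) -> List[Param]:
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> List[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: List[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
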