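"""Layer objects with explicit forward/backward passes.

Each layer takes a list of input arrays and returns one output; backward
takes the output gradient and returns per-input gradients, accumulating
parameter gradients on the layer.  Randomness (init, dropout) flows
through the generator handed in by the caller — no global state.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .ops import (
    conv2d_backward,
    conv2d_forward,
    conv_transpose2d_backward,
    conv_transpose2d_forward,
)


class Layer:
    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, xs: List[np.ndarray], training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> List[np.ndarray]:
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kernel_size, stride=1, init_std=0.02, rng=None):
        k = kernel_size
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k - 1) // 2
        self.w = rng.normal(0.0, init_std, size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, xs, training, rng):
        y, self._cache = conv2d_forward(xs[0], self.w, self.b, self.stride, self.pad)
        return y

    def backward(self, gy):
        gx, gw, gb = conv2d_backward(gy, self.w, self._cache, self.stride, self.pad)
        self.gw += gw
        self.gb += gb
        return [gx]


class ConvTranspose2D(Layer):
    def __init__(self, c_in, c_out, kernel_size, stride=2, init_std=0.02, rng=None):
        k = kernel_size
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k - 1) // 2
        self.out_pad = stride - 1
        self.w = rng.normal(0.0, init_std, size=(c_in, c_out, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, xs, training, rng):
        y, self._cache = conv_transpose2d_forward(
            xs[0], self.w, self.b, self.stride, self.pad, self.out_pad
        )
        return y

    def backward(self, gy):
        gx, gw, gb = conv_transpose2d_backward(gy, self.w, self._cache, self.stride, self.pad)
        self.gw += gw
        self.gb += gb
        return [gx]


class BatchNorm2D(Layer):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, xs, training, rng):
        x = xs[0]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gy):
        xhat, inv, training, shape = self._cache
        self.ggamma += (gy * xhat).sum(axis=(0, 2, 3))
        self.gbeta += gy.sum(axis=(0, 2, 3))
        g = gy * self.gamma[None, :, None, None]
        if not training:
            return [g * inv[None, :, None, None]]
        n = shape[0] * shape[2] * shape[3]
        gxhat_sum = (g * xhat).sum(axis=(0, 2, 3))
        gx = (
            g
            - g.sum(axis=(0, 2, 3))[None, :, None, None] / n
            - xhat * gxhat_sum[None, :, None, None] / n
        ) * inv[None, :, None, None]
        return [gx]


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, xs, training, rng):
        x = xs[0]
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return [np.where(self._mask, gy, self.slope * gy)]


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, xs, training, rng):
        x = np.clip(xs[0], -60.0, 60.0)
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return [gy * self._y * (1.0 - self._y)]


class Dropout(Layer):
    def __init__(self, rate=0.5):
        self.rate = rate
        self._mask = None

    def forward(self, xs, training, rng):
        x = xs[0]
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return [gy]
        return [gy * self._mask]


class Concat(Layer):
    def __init__(self):
        self._splits = None

    def forward(self, xs, training, rng):
        self._splits = np.cumsum([x.shape[1] for x in xs])[:-1]
        return np.concatenate(xs, axis=1)

    def backward(self, gy):
        return [np.ascontiguousarray(g) for g in np.split(gy, self._splits, axis=1)]


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def dice_loss_and_grad(p: np.ndarray, y: np.ndarray, eps: float = 1.0):
    """Soft dice loss (1 - DSC) averaged over the batch, with dL/dp."""
    n = p.shape[0]
    pf = p.reshape(n, -1).astype(np.float64)
    yf = y.reshape(n, -1).astype(np.float64)
    inter = (pf * yf).sum(axis=1)
    sums = pf.sum(axis=1) + yf.sum(axis=1)
    dice = (2.0 * inter + eps) / (sums + eps)
    loss = float(np.mean(1.0 - dice))
    grad = -(2.0 * yf * (sums + eps)[:, None] - (2.0 * inter + eps)[:, None]) / (
        (sums + eps) ** 2
    )[:, None]
    grad /= n
    return loss, grad.reshape(p.shape).astype(np.float32)


def dice_coefficient(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Hard DSC of two binary arrays (1.0 when both are empty)."""
    a = pred_mask.astype(bool)
    b = ref_mask.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
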