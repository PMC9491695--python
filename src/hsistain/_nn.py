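"""Minimal convolutional-network engine (numpy, manual backprop).

Single-sample (batch size one) layers operating on ``(C, H, W)`` float32
tensors, with explicit ``forward``/``backward`` passes and an Adam
optimizer.  This is deliberately small: exactly the pieces the
conditional-GAN translator needs — strided 3x3/4x4 convolutions via
im2col, instance normalization, leaky ReLU / ReLU / tanh, nearest
upsampling — with gradients derived by hand and checked against finite
differences in the test suite.  Pure numpy keeps training bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "InstanceNorm", "LeakyReLU", "ReLU", "Tanh",
           "Upsample2", "Sequential", "Adam"]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """x (C,H,W) -> cols (oh*ow, C*k*k); also returns (oh, ow, padded shape)."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    hp, wp = xp.shape[1:]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = np.empty((c, k, k, oh, ow), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(c * k * k, oh * ow).T, oh, ow, (hp, wp)


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int, padded_shape):
    """Scatter-add column gradients back to the input tensor."""
    c, h, w = x_shape
    hp, wp = padded_shape
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    g = gcols.T.reshape(c, k, k, oh, ow)
    gx = np.zeros((c, hp, wp), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            gx[:, i:i + stride * oh:stride, j:j + stride * ow:stride] += g[:, i, j]
    if pad:
        gx = gx[:, pad:hp - pad, pad:wp - pad]
    return gx


class Conv2d:
    """2-D convolution with 'same'-style zero padding ``pad = (k-1)//2``."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch * k * k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow, padded = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._padded = cols, padded
        out = cols @ self.weight.value.T + self.bias.value
        return out.T.reshape(self.out_ch, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        oc, oh, ow = grad.shape
        gflat = grad.reshape(oc, oh * ow).T  # (ohw, oc)
        self.weight.grad += gflat.T @ self._cols
        self.bias.grad += gflat.sum(axis=0)
        gcols = gflat @ self.weight.value
        return _col2im(gcols, self._x_shape, self.k, self.stride, self.pad, self._padded)


class InstanceNorm:
    """Per-channel normalization over the spatial axes, with affine."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xn = (x - mu) * self._inv
        return self.gamma.value[:, None, None] * self._xn + self.beta.value[:, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[1] * grad.shape[2]
        self.gamma.grad += (grad * self._xn).sum(axis=(1, 2))
        self.beta.grad += grad.sum(axis=(1, 2))
        gxn = grad * self.gamma.value[:, None, None]
        # d/dx of (x - mu) / sqrt(var + eps)
        return self._inv * (
            gxn
            - gxn.mean(axis=(1, 2), keepdims=True)
            - self._xn * (gxn * self._xn).mean(axis=(1, 2), keepdims=True)
        ).astype(DTYPE)


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y * self._y)


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c, h, w = grad.shape
        return grad.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adaptive-moment optimizer with the default moment constants."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
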