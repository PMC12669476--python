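"""Minimal conv-net primitives with manual backpropagation.

Implements exactly the layers the pix2pix-style virtual-staining model
needs — strided convolution, transposed convolution, instance norm,
leaky-ReLU/ReLU/tanh activations, binary cross-entropy on logits, L1 loss,
and Adam — on plain numpy arrays in NCHW layout. Every layer caches its
forward inputs and returns the gradient with respect to its input from
``backward``; parameter gradients accumulate on :class:`Param` objects. A
numeric gradient check in the test suite guards the implementation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "ConvTranspose2d", "InstanceNorm", "LeakyReLU",
    "ReLU", "Tanh", "Sequential", "Adam", "bce_with_logits", "l1_loss",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def set_training(self, flag: bool) -> None:
        pass

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """k x k convolution, stride s, zero padding p (NCHW)."""

    def __init__(self, c_in, c_out, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.w = Param(_he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Param(np.zeros(c_out))
        self._x_pad = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, hp, wp = xp.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        w = self.w.value
        out = np.zeros((n, w.shape[0], ho, wo))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s]
                out += np.einsum("oc,nchw->nohw", w[:, :, ki, kj], xs, optimize=True)
        out += self.b.value[None, :, None, None]
        self._x_pad = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        xp = self._x_pad
        n, c, hp, wp = xp.shape
        ho, wo = dout.shape[2], dout.shape[3]
        w = self.w.value
        dxp = np.zeros_like(xp)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s]
                self.w.grad[:, :, ki, kj] += np.einsum("nohw,nchw->oc", dout, xs, optimize=True)
                dxp[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s] += np.einsum(
                    "oc,nohw->nchw", w[:, :, ki, kj], dout, optimize=True)
        return dxp[:, :, p:hp - p, p:wp - p] if p else dxp


class ConvTranspose2d(Module):
    """Transposed k x k convolution, stride s, padding p; doubles H, W for
    the pix2pix choice k=4, s=2, p=1."""

    def __init__(self, c_in, c_out, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.w = Param(_he_init(rng, (c_in, c_out, k, k), c_in * k * k // (stride * stride)))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        n, c, h, w_ = x.shape
        ho_full, wo_full = (h - 1) * s + k, (w_ - 1) * s + k
        out = np.zeros((n, self.w.value.shape[1], ho_full, wo_full))
        wv = self.w.value
        for ki in range(k):
            for kj in range(k):
                out[:, :, ki:ki + h * s:s, kj:kj + w_ * s:s] += np.einsum(
                    "co,nchw->nohw", wv[:, :, ki, kj], x, optimize=True)
        out = out[:, :, p:ho_full - p, p:wo_full - p] if p else out
        out += self.b.value[None, :, None, None]
        self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        x = self._x
        n, c, h, w_ = x.shape
        ho_full, wo_full = (h - 1) * s + k, (w_ - 1) * s + k
        dfull = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p))) if p else dout
        self.b.grad += dout.sum(axis=(0, 2, 3))
        wv = self.w.value
        dx = np.zeros_like(x)
        for ki in range(k):
            for kj in range(k):
                ds = dfull[:, :, ki:ki + h * s:s, kj:kj + w_ * s:s]
                self.w.grad[:, :, ki, kj] += np.einsum("nchw,nohw->co", x, ds, optimize=True)
                dx += np.einsum("co,nohw->nchw", wv[:, :, ki, kj], ds, optimize=True)
        return dx


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation with learnable scale/shift.

    Running channel statistics are tracked during training and used in eval
    mode, so inference is a pointwise map independent of the spatial extent
    of the input (required for consistent tiled inference)."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.training = True
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var[None, :, None, None] + self.eps)
            xhat = (x - mu) * inv
            return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        m = self.momentum
        self.running_mean += m * (x.mean(axis=(0, 2, 3)) - self.running_mean)
        self.running_var += m * (x.var(axis=(0, 2, 3)) - self.running_var)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * g
        m = xhat.shape[2] * xhat.shape[3]
        return (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)) * inv


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Module):
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def set_training(self, flag: bool) -> None:
        for l in self.layers:
            l.set_training(flag)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Param], lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    t = np.full_like(logits, target)
    # stable: log(1+exp(-|z|)) + max(z,0) - z*t
    loss = np.mean(np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits))))
    sig = 1.0 / (1.0 + np.exp(-logits))
    grad = (sig - t) / logits.size
    return float(loss), grad


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error; returns (loss, dloss/dpred)."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
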