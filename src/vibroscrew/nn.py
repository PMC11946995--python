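"""Minimal CPU neural-network layers with manual backpropagation.

Implements exactly what the spectrogram classifier needs — 2-D convolution,
batch normalization, ReLU, 2x2 max pooling, global average pooling, dense
layers, squeeze-and-excitation gating, binary cross-entropy on logits, and
Adam — in float32 numpy.  Feature maps are laid out channels-last (N, H, W, C)
and convolutions are evaluated as k*k shifted GEMMs (one per tap), which
keeps memory bounded and lets BLAS do the work.

All randomness flows through an explicit ``numpy.random.Generator``; forward
and backward passes are pure numpy, so training is bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Dense",
    "SEBlock",
    "bce_with_logits",
    "sigmoid",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def parameters(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """3x3 (or 1x1) convolution on (N, H, W, C), He-initialized, no bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        # weight stored per tap: (k, k, c_in, c_out)
        self.w = Param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)))
        self._xp: np.ndarray | None = None

    def _tap_slices(self, oh: int, ow: int):
        k, s = self.k, self.stride
        for i in range(k):
            for j in range(k):
                yield i, j, slice(i, i + s * (oh - 1) + 1, s), slice(
                    j, j + s * (ow - 1) + 1, s
                )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        c_out = self.w.data.shape[3]
        # few input channels: one im2col GEMM; otherwise accumulate per tap
        # (measured crossover on contiguous NHWC maps)
        if k * k * c <= 16:
            cols = np.empty((n * oh * ow, k * k * c), dtype=np.float32)
            view = cols.reshape(n, oh, ow, k * k, c)
            for i, j, sh, sw in self._tap_slices(oh, ow):
                view[:, :, :, i * k + j, :] = xp[:, sh, sw, :]
            y = cols @ self.w.data.reshape(k * k * c, c_out)
        else:
            y = np.zeros((n * oh * ow, c_out), dtype=np.float32)
            for i, j, sh, sw in self._tap_slices(oh, ow):
                y += xp[:, sh, sw, :].reshape(-1, c) @ self.w.data[i, j]
        if train:
            self._xp, self._shape = xp, (n, h, w, c, oh, ow)
        return y.reshape(n, oh, ow, c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c, oh, ow = self._shape
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        c_out = self.w.data.shape[3]
        dyf = dy.reshape(-1, c_out)
        dxp = np.zeros_like(xp)
        for i, j, sh, sw in self._tap_slices(oh, ow):
            xs = xp[:, sh, sw, :].reshape(-1, c)
            self.w.grad[i, j] += xs.T @ dyf
            dxp[:, sh, sw, :] += (dyf @ self.w.data[i, j].T).reshape(n, oh, ow, c)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def parameters(self) -> list[Param]:
        return [self.w]


class BatchNorm2d(Layer):
    """Channel batch normalization on (N, H, W, C).

    Running statistics are warm-started from the first batch, then updated by
    an exponential moving average; this keeps inference statistics usable
    even after short trainings.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._initialized = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[-1]
        xf = x.reshape(-1, c)
        if train:
            mean = xf.mean(axis=0)
            var = xf.var(axis=0)
            if not self._initialized:
                self.running_mean[...] = mean
                self.running_var[...] = var
                self._initialized = True
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        scale = self.gamma.data * inv
        shift = self.beta.data - mean * scale
        y = x * scale + shift
        if train:
            self._x, self._mean, self._inv = x, mean.astype(np.float32), inv
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mean, inv = self._x, self._mean, self._inv
        c = dy.shape[-1]
        dyf = dy.reshape(-1, c)
        xf = x.reshape(-1, c)
        xhat = (xf - mean) * inv
        sum_dy = dyf.sum(axis=0)
        sum_dy_xhat = (dyf * xhat).sum(axis=0)
        self.gamma.grad += sum_dy_xhat
        self.beta.grad += sum_dy
        m = dyf.shape[0]
        g = self.gamma.data * inv
        dx = g * (dyf - sum_dy / m - xhat * (sum_dy_xhat / m))
        self._x = None
        return dx.reshape(dy.shape).astype(np.float32, copy=False)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xr = x[:, : 2 * oh, : 2 * ow, :].reshape(n, oh, 2, ow, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, (n, h, w, c)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        dxr = np.zeros((n, oh, ow, c, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : 2 * oh, : 2 * ow, :] = dxr.reshape(n, 2 * oh, 2 * ow, c)
        self._idx = None
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(
            dy[:, None, None, :] / (h * w), (n, h, w, c)
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_out, d_in)))
        self.b = Param(np.zeros(d_out))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.data
        self._x = None
        return dx

    def parameters(self) -> list[Param]:
        return [self.w, self.b]


class SEBlock(Layer):
    """Squeeze-and-excitation channel gating with reduction ratio r.

    Global average over the spatial dims, a C -> C/r bottleneck with ReLU,
    expansion back to C with a logistic squash, and channel-wise rescaling.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator | None = None):
        if c % r != 0:
            raise ValueError(f"channel count {c} not divisible by reduction {r}")
        self.fc1 = Dense(c, c // r, rng=rng)
        self.fc2 = Dense(c // r, c, rng=rng)
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))
        a = self.relu.forward(self.fc1.forward(z, train), train)
        s = sigmoid(self.fc2.forward(a, train)).astype(np.float32)
        if train:
            self._x, self._s, self._hw = x, s, (h, w)
        return x * s[:, None, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        h, w = self._hw
        dx = dy * s[:, None, None, :]
        ds = (dy * x).sum(axis=(1, 2))
        da2 = (ds * s * (1.0 - s)).astype(np.float32)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(da2)))
        dx += (dz / (h * w))[:, None, None, :]
        self._x = None
        return dx.astype(np.float32, copy=False)

    def parameters(self) -> list[Param]:
        return self.fc1.parameters() + self.fc2.parameters()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    # log(1 + e^z) evaluated stably
    loss = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
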