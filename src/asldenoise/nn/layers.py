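"""Volumetric neural-network layers with explicit backward passes.

All activations use the layout (N, C, D, H, W).  Each layer caches what its
backward pass needs only when ``training=True``; inference passes keep no
state.  Gradients accumulate into ``Tensor.grad`` until ``zero_grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Layer", "Conv3d", "ConvTranspose3d", "BatchNorm3d",
           "LeakyReLU", "MaxPool3d", "Dropout"]


class Tensor:
    """A trainable parameter: value plus accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Tensor]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, D*H*W, C*k^3) patch matrix, same padding."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    n, c, d, h, w = v.shape[:5]
    # (N, D, H, W, C, k, k, k) -> (N, P, C*k^3)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                                ).reshape(n, d * h * w, c * k ** 3)


class Conv3d(Layer):
    """3D convolution, stride 1, same padding, odd kernel (default 3)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k ** 3
        std = np.sqrt(2.0 / fan_in)  # He init for (leaky-)ReLU stacks
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.w = Tensor(rng.normal(0, std, (out_ch, fan_in)).astype(dtype),
                        "conv.w")
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        n = x.shape[0]
        spatial = x.shape[2:]
        cols = _im2col(x, self.k)
        y = cols @ self.w.value.T + self.b.value
        if training:
            self._cache = (cols, spatial)
        return np.ascontiguousarray(
            y.transpose(0, 2, 1)).reshape(n, self.out_ch, *spatial)

    def backward(self, dy):
        cols, spatial = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_ch, -1).transpose(0, 2, 1)  # (N, P, O)
        self.w.grad += np.einsum("npo,npc->oc", dyf, cols)
        self.b.grad += dyf.sum(axis=(0, 1))
        # input gradient = conv of dy with spatially flipped, transposed weights
        wf = self.w.value.reshape(self.out_ch, self.in_ch,
                                  self.k, self.k, self.k)
        wf = wf[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        wf = wf.reshape(self.in_ch, self.out_ch * self.k ** 3)
        dcols = _im2col(dy, self.k)
        dx = dcols @ wf.T
        self._cache = None
        return np.ascontiguousarray(
            dx.transpose(0, 2, 1)).reshape(n, self.in_ch, *spatial)


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (resolution doubler)."""

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_ch)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Tensor(rng.normal(0, std, (in_ch, out_ch, 2, 2, 2)
                                   ).astype(dtype), "upconv.w")
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), "upconv.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=True):
        n, _, d, h, w = x.shape
        t = np.tensordot(x, self.w.value, axes=([1], [0]))
        # (N, D, H, W, O, 2, 2, 2) -> (N, O, D, 2, H, 2, W, 2)
        y = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, self.out_ch, 2 * d, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None, None]
        if training:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        n, _, d, h, w = x.shape
        dyb = dy.reshape(n, self.out_ch, d, 2, h, 2, w, 2)
        dyb = dyb.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # (N,D,H,W,O,2,2,2)
        self.w.grad += np.tensordot(x, dyb,
                                    axes=([0, 2, 3, 4], [0, 1, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        dx = np.tensordot(dyb, self.w.value,
                          axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self._cache = None
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    AXES = (0, 2, 3, 4)

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Tensor(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _bc(self, v):
        return v[None, :, None, None, None]

    def forward(self, x, training=True):
        if training:
            mu = x.mean(axis=self.AXES)
            var = x.var(axis=self.AXES)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu)) * self._bc(inv_std)
        y = self._bc(self.gamma.value) * xhat + self._bc(self.beta.value)
        if training:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, dy):
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.gamma.grad += (dy * xhat).sum(axis=self.AXES)
        self.beta.grad += dy.sum(axis=self.AXES)
        dxhat = dy * self._bc(self.gamma.value)
        s1 = dxhat.sum(axis=self.AXES)
        s2 = (dxhat * xhat).sum(axis=self.AXES)
        dx = (dxhat - self._bc(s1) / m - xhat * self._bc(s2) / m) \
            * self._bc(inv_std)
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._cache = None

    def forward(self, x, training=True):
        y = np.where(x > 0, x, self.slope * x)
        if training:
            self._cache = x > 0
        return y

    def backward(self, dy):
        pos = self._cache
        self._cache = None
        return np.where(pos, dy, self.slope * dy)


class MaxPool3d(Layer):
    """2x2x2 max pooling; ties route the gradient to the first maximum."""

    def forward(self, x, training=True):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, (n, c, d, h, w))
        return y

    def backward(self, dy):
        idx, (n, c, d, h, w) = self._cache
        dxr = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        dxr = dxr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        self._cache = None
        return dxr


class Dropout(Layer):
    """Inverted dropout; a no-op at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._cache = None

    def forward(self, x, training=True):
        if not training or self.rate == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate)
        scale = 1.0 / (1.0 - self.rate)
        self._cache = keep
        return x * keep * scale

    def backward(self, dy):
        if self._cache is None:
            return dy
        keep = self._cache
        self._cache = None
        return dy * keep / (1.0 - self.rate)
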