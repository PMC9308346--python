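"""Convolutional and dense layers on numpy, NCHW layout."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter


class GeometryError(ValueError):
    """Raised when a layer's input size is inadmissible for its geometry."""


def conv_out_size(x: int, k: int, s: int = 1, p: int = 0, d: int = 1) -> int:
    """Spatial output size of a convolution: floor((x - k - (k-1)(d-1) + 2p)/s) + 1."""
    y = (x - k - (k - 1) * (d - 1) + 2 * p) // s + 1
    return y


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True, *,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by "
                f"groups={groups}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        # He-normal: appropriate for the ReLU nonlinearities that follow
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels // groups,
                        kernel_size, kernel_size))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def out_size(self, x: int) -> int:
        return conv_out_size(x, self.kernel_size, self.stride,
                             self.padding, self.dilation)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p, d, g = (self.kernel_size, self.stride, self.padding,
                         self.dilation, self.groups)
        ke = (k - 1) * d + 1
        Ho, Wo = self.out_size(H), self.out_size(W)
        if Ho <= 0 or Wo <= 0:
            raise GeometryError(
                f"input {H}x{W} too small for conv k={k} s={s} p={p} d={d}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        view = sliding_window_view(xp, (ke, ke), axis=(2, 3))
        view = view[:, :, ::s, ::s, ::d, ::d]
        cg, og = C // g, self.out_channels // g
        v = view.reshape(N, g, cg, Ho, Wo, k, k)
        w = self.weight.data.reshape(g, og, cg, k, k)
        y = np.einsum("ngchwkl,gdckl->ngdhw", v, w, optimize=True)
        y = np.ascontiguousarray(y.reshape(N, self.out_channels, Ho, Wo))
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (v, x.shape, xp.shape, Ho, Wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        v, x_shape, xp_shape, Ho, Wo = self._cache
        N, C, H, W = x_shape
        k, s, p, d, g = (self.kernel_size, self.stride, self.padding,
                         self.dilation, self.groups)
        cg, og = C // g, self.out_channels // g
        dyg = dy.reshape(N, g, og, Ho, Wo)
        dw = np.einsum("ngchwkl,ngdhw->gdckl", v, dyg, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        w = self.weight.data.reshape(g, og, cg, k, k)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for ki in range(k):
            hi = ki * d
            for kj in range(k):
                wj = kj * d
                t = np.einsum("ngdhw,gdc->ngchw", dyg, w[:, :, :, ki, kj],
                              optimize=True)
                dxp[:, :,
                    hi:hi + (Ho - 1) * s + 1:s,
                    wj:wj + (Wo - 1) * s + 1:s] += t.reshape(N, C, Ho, Wo)
        if p:
            return dxp[:, :, p:p + H, p:p + W]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum  # running = m*running + (1-m)*batch
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not self.training:
            return dxhat * inv[None, :, None, None]
        # batch statistics participate in the forward pass
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        dx = (dxhat - t1.transpose(1, 0, 2, 3) / m
              - xhat * t2.transpose(1, 0, 2, 3) / m) * inv[None, :, None, None]
        return dx


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def out_size(self, x: int) -> int:
        return conv_out_size(x, self.kernel_size, self.stride, self.padding)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        Ho, Wo = self.out_size(H), self.out_size(W)
        if Ho <= 0 or Wo <= 0:
            raise GeometryError(f"input {H}x{W} too small for pool k={k} s={s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        view = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        v = view.reshape(N, C, Ho, Wo, k * k)
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape, Ho, Wo)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, x_shape, xp_shape, Ho, Wo = self._cache
        N, C, H, W = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        n_i, c_i, h_i, w_i = np.indices((N, C, Ho, Wo), sparse=False)
        rows = h_i * s + idx // k
        cols = w_i * s + idx % k
        np.add.at(dxp, (n_i, c_i, rows, cols), dy)
        if p:
            return dxp[:, :, p:p + H, p:p + W]
        return dxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        # Xavier-uniform
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(
            rng.uniform(-limit, limit, (out_features, in_features)).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float = 0.5, *, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class GlobalAvgPool(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W),
                               self._shape).copy()


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


def upsample_nearest(x: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return x
    return x.repeat(factor, axis=2).repeat(factor, axis=3)


def upsample_nearest_backward(dy: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return dy
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // factor, factor,
                      W // factor, factor).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          normalizer: float | None = None):
    """Mean (or ``1/normalizer``-scaled sum) cross entropy and its gradient.

    ``logits``: (N, K); ``labels``: (N,) integer class ids.
    Returns ``(loss, dlogits)``.
    """
    n, k = logits.shape
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError("label out of range")
    norm = float(n) if normalizer is None else float(normalizer)
    p = softmax(logits, axis=1)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).sum() / norm
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / norm
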