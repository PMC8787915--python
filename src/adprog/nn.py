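"""Minimal NumPy neural-network engine for small 3-D multimodal models.

Layers implement ``forward(x, training)`` / ``backward(grad)`` with cached
activations and analytic gradients; every layer is gradient-checked
against central finite differences in the test suite.  The engine covers
exactly what the parameter-efficient classifier needs:

* 3-D convolution (im2col + GEMM) and depthwise 3-D convolution with
  "same" padding and strides, sharing a precomputed scatter index for the
  input gradient;
* batch normalization with running statistics;
* ELU, dense layers, flatten, and a fused softmax cross-entropy loss;
* plain SGD with per-layer L2 weight decay and stepwise exponential
  learning-rate decay.

All computation is deterministic for a fixed seed: initialization draws
from one :class:`numpy.random.Generator` and the only numerical kernels
are NumPy GEMMs and bincounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "DepthwiseConv3d",
    "BatchNorm",
    "ELU",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    decay: bool = False  # subject to L2 weight decay

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' padding."""
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class _ConvBase(Layer):
    """Shared im2col plumbing for full and depthwise 3-D convolutions."""

    def __init__(self, kernel: int, stride: int) -> None:
        self.k = kernel
        self.s = stride
        self._cache_shape: tuple | None = None
        self._idx: np.ndarray | None = None  # (P * C * k^3,) scatter index
        self._pads: tuple | None = None
        self._out_spatial: tuple | None = None

    def _cols(self, x: np.ndarray) -> np.ndarray:
        """Patches as (B, P, C, k^3); also prepares the scatter index."""
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        k, s = self.k, self.s
        if self._cache_shape != x.shape[1:]:
            outs, pads = [], []
            for size in spatial:
                o, pb, pa = _same_pad(size, k, s)
                outs.append(o)
                pads.append((pb, pa))
            self._out_spatial = tuple(outs)
            self._pads = tuple(pads)
            padded = tuple(size + pb + pa for size, (pb, pa) in zip(spatial, pads))
            Dp, Hp, Wp = padded
            od, oh, ow = np.meshgrid(*[np.arange(o) for o in outs], indexing="ij")
            kd, kh, kw = np.meshgrid(*([np.arange(k)] * 3), indexing="ij")
            c = np.arange(C)
            # flat index into (C, Dp, Hp, Wp), laid out as (P, C, k^3)
            pd = (od.ravel()[:, None, None] * s + kd.ravel()[None, None, :])
            ph = (oh.ravel()[:, None, None] * s + kh.ravel()[None, None, :])
            pw = (ow.ravel()[:, None, None] * s + kw.ravel()[None, None, :])
            idx = ((c[None, :, None] * Dp + pd) * Hp + ph) * Wp + pw
            self._idx = idx.ravel()
            self._padded = padded
            self._cache_shape = x.shape[1:]
        pads = ((0, 0), (0, 0), *self._pads)
        xp = np.pad(x, pads)
        win = sliding_window_view(xp, (self.k,) * 3, axis=(2, 3, 4))
        win = win[:, :, :: self.s, :: self.s, :: self.s]
        # (B, C, Do, Ho, Wo, k, k, k) -> (B, P, C, k^3)
        B = x.shape[0]
        P = int(np.prod(self._out_spatial))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            B, P, C, self.k**3
        )
        return cols

    def _scatter(self, dcols: np.ndarray, in_shape: tuple) -> np.ndarray:
        """col2im: accumulate (B, P, C, k^3) gradients back onto the input."""
        B, C = in_shape[:2]
        padded_size = C * int(np.prod(self._padded))
        dxp = np.empty((B, padded_size), dtype=dcols.dtype)
        flat = dcols.reshape(B, -1)
        for b in range(B):
            dxp[b] = np.bincount(self._idx, weights=flat[b], minlength=padded_size)
        dxp = dxp.reshape(B, C, *self._padded)
        slices = tuple(
            slice(pb, pb + size) for (pb, pa), size in zip(self._pads, in_shape[2:])
        )
        return dxp[(slice(None), slice(None), *slices)]


class Conv3d(_ConvBase):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 input_layer: bool = False) -> None:
        super().__init__(kernel, stride)
        self.input_layer = input_layer  # skip the (unused) input gradient
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ELU-family activations
        self.W = Param(rng.normal(0, scale, (fan_in, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self) -> int:
        return self.W.value.size + self.b.value.size

    def forward(self, x, training=False):
        B = x.shape[0]
        cols = self._cols(x)  # (B, P, C, k^3)
        P = cols.shape[1]
        cols2 = cols.reshape(B * P, -1)
        self._x_shape = x.shape
        self._cols2 = cols2
        out = (cols2 @ self.W.value + self.b.value).reshape(B, P, -1)
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(
            B, self.c_out, *self._out_spatial
        )

    def backward(self, grad):
        B = grad.shape[0]
        g = np.ascontiguousarray(
            grad.reshape(B, self.c_out, -1).transpose(0, 2, 1)
        ).reshape(-1, self.c_out)  # (B*P, F)
        self.W.grad += self._cols2.T @ g
        self.b.grad += g.sum(axis=0)
        if self.input_layer:
            return None
        dcols = g @ self.W.value.T  # (B*P, C*k^3)
        return self._scatter(dcols.reshape(B, -1, self.c_in, self.k**3), self._x_shape)


class DepthwiseConv3d(_ConvBase):
    """One k^3 filter per channel; no cross-channel mixing."""

    def __init__(self, channels: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__(kernel, stride)
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / kernel**3)
        self.W = Param(rng.normal(0, scale, (channels, kernel**3)).astype(dtype))
        self.b = Param(np.zeros(channels, dtype=dtype))
        self.channels = channels

    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self) -> int:
        return self.W.value.size + self.b.value.size

    def forward(self, x, training=False):
        B = x.shape[0]
        cols = self._cols(x)  # (B, P, C, k^3)
        self._x_shape = x.shape
        self._patches = cols
        out = np.einsum("bpck,ck->bpc", cols, self.W.value, optimize=True) + self.b.value
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(
            B, self.channels, *self._out_spatial
        )

    def backward(self, grad):
        B = grad.shape[0]
        g = grad.reshape(B, self.channels, -1).transpose(0, 2, 1)  # (B, P, C)
        self.W.grad += np.einsum("bpck,bpc->ck", self._patches, g, optimize=True)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g[..., None] * self.W.value[None, None]  # (B, P, C, k^3)
        return self._scatter(dcols, self._x_shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, spatial) axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(channels, dtype=dtype)
        self.run_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training=False):
        axes = self._axes(x)
        shape = self._bshape(x)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, training, x.shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        xhat, inv, axes, shape, training, x_shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gg = self.gamma.value.reshape(shape)
        if not training:
            return grad * gg * inv.reshape(shape)
        m = np.prod([x_shape[a] for a in axes])
        dxhat = grad * gg
        return (
            inv.reshape(shape)
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes).reshape(shape)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
            )
        )


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha

    def forward(self, x, training=False):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._y = y
        return y

    def backward(self, grad):
        return grad * np.where(self._y > 0, 1.0, self._y + self.alpha)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at rate 0 or in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 decay: bool = True, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0, scale, (n_in, n_out)).astype(dtype), )
        self.W.decay = decay
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self) -> int:
        return self.W.value.size + self.b.value.size

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype), probs


class SGD:
    """Plain SGD with L2 weight decay on flagged params and stepwise
    exponential learning-rate decay (lr * drop^(epoch // period))."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 lr_drop: float = 0.5, drop_period: int = 10) -> None:
        self.params = params
        self.lr0 = lr
        self.weight_decay = weight_decay
        self.lr_drop = lr_drop
        self.drop_period = max(int(drop_period), 1)
        self.lr = lr

    def set_epoch(self, epoch: int) -> None:
        self.lr = self.lr0 * self.lr_drop ** (epoch // self.drop_period)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + self.weight_decay * p.value
            p.value -= self.lr * g
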