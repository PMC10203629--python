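"""Minimal NumPy neural-network engine with manual backpropagation.

Implements exactly the layer vocabulary the LightMixer architecture needs:
grouped/depthwise 2-D convolution, batch normalization, the Phish
activation, pooling, dropout, a linear head, residual wiring, Adam, and
softmax cross-entropy.  All arithmetic is float32; convolutions are lowered
to BLAS matrix products through im2col (dense case) or to shifted-slice
accumulation (depthwise case), which covers every layer the model uses.

The engine is deliberately small: layers cache what their backward pass
needs on ``self``, so a module instance is single-stream (one forward, then
one backward).  That is sufficient for plain SGD-style training loops.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

DTYPE = np.float32

# Phish / GELU constants, double precision, cast at use site.
_GELU_C = math.sqrt(2.0 / math.pi)
_GELU_A = 0.044715


def gelu_tanh_array(x: np.ndarray) -> np.ndarray:
    """Tanh-approximation GELU: 0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x**3)))."""
    x = np.asarray(x)
    t = _GELU_C * (x + _GELU_A * x * x * x)
    return 0.5 * x * (1.0 + np.tanh(t))


def phish_array(x: np.ndarray) -> np.ndarray:
    """Phish activation: x * tanh(GELU(x)). Nonnegative, smooth, ~identity for large x."""
    x = np.asarray(x)
    return x * np.tanh(gelu_tanh_array(x))


def phish_grad_array(x: np.ndarray) -> np.ndarray:
    """Analytic derivative of Phish, used by backprop and the gradient checks."""
    x = np.asarray(x)
    t = _GELU_C * (x + _GELU_A * x * x * x)
    th_t = np.tanh(t)
    g = 0.5 * x * (1.0 + th_t)
    dg = 0.5 * (1.0 + th_t) + 0.5 * x * (1.0 - th_t * th_t) * _GELU_C * (
        1.0 + 3.0 * _GELU_A * x * x
    )
    th_g = np.tanh(g)
    return th_g + x * (1.0 - th_g * th_g) * dg


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base layer: forward(x, train) -> y, backward(dy) -> dx."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> Iterator[Parameter]:
        return iter(())

    def modules(self) -> Iterator["Module"]:
        yield self

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def num_parameters(self) -> int:
        """Runtime enumeration of trainable values (the framework-side count)."""
        return sum(p.size for p in self.parameters())

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _pad2d(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


class Conv2d(Module):
    """2-D convolution (cross-correlation) with optional channel grouping.

    Supports the two cases the architecture uses: dense (groups=1) and
    depthwise (groups == in_channels == out_channels).  Weight layout is
    (out_channels, in_channels // groups, kh, kw).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] = (1, 1),
        padding: tuple[int, int] = (0, 0),
        groups: int = 1,
        bias: bool = True,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        if groups not in (1, in_channels) or (
            groups == in_channels and groups > 1 and out_channels != in_channels
        ):
            raise NotImplementedError(
                "only dense (groups=1) and depthwise (groups=in=out) convolutions"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        self.groups = groups
        kh, kw = self.kernel
        self.weight = Parameter(
            np.zeros((out_channels, in_channels // groups, kh, kw)), "weight"
        )
        self.bias = Parameter(np.zeros(out_channels), "bias") if bias else None
        self.last_output_shape: tuple[int, ...] | None = None

    @property
    def depthwise(self) -> bool:
        return self.groups > 1

    def init(self, rng: np.random.Generator) -> None:
        kh, kw = self.kernel
        fan_in = (self.in_channels // self.groups) * kh * kw
        std = math.sqrt(2.0 / fan_in)
        self.weight.value = rng.normal(0.0, std, self.weight.value.shape).astype(DTYPE)
        if self.bias is not None:
            self.bias.value = np.zeros(self.out_channels, dtype=DTYPE)

    def parameters(self) -> Iterator[Parameter]:
        yield self.weight
        if self.bias is not None:
            yield self.bias

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        return (h + 2 * ph - kh) // sh + 1, (w + 2 * pw - kw) // sw + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, _, h, w = x.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        ho, wo = self._out_hw(h, w)
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for kernel {self.kernel}")
        xp = _pad2d(x, *self.padding)
        if self.depthwise:
            y = np.zeros((n, self.out_channels, ho, wo), dtype=DTYPE)
            wv = self.weight.value  # (C, 1, kh, kw)
            for u in range(kh):
                for v in range(kw):
                    y += (
                        xp[:, :, u : u + sh * ho : sh, v : v + sw * wo : sw]
                        * wv[None, :, 0, u, v, None, None]
                    )
            self._cache = (xp, x.shape, (ho, wo))
        else:
            s = xp.strides
            pat = np.lib.stride_tricks.as_strided(
                xp,
                (n, self.in_channels, kh, kw, ho, wo),
                (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
                writeable=False,
            )
            cols = pat.reshape(n, self.in_channels * kh * kw, ho * wo)
            wf = self.weight.value.reshape(self.out_channels, -1)
            y = np.matmul(wf, cols).reshape(n, self.out_channels, ho, wo)
            self._cache = (cols, xp.shape, x.shape, (ho, wo))
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if self.depthwise:
            xp, x_shape, (ho, wo) = self._cache
            wv = self.weight.value
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    sl = np.s_[:, :, u : u + sh * ho : sh, v : v + sw * wo : sw]
                    self.weight.grad[:, 0, u, v] += (dy * xp[sl]).sum(axis=(0, 2, 3))
                    dxp[sl] += dy * wv[None, :, 0, u, v, None, None]
            dx = dxp[:, :, ph : ph + x_shape[2], pw : pw + x_shape[3]]
            return np.ascontiguousarray(dx)
        cols, xp_shape, x_shape, (ho, wo) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_channels, ho * wo)
        wf = self.weight.value.reshape(self.out_channels, -1)
        dwf = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += dwf.reshape(self.weight.value.shape)
        dcols = np.matmul(wf.T, dyf)  # (n, C*kh*kw, L)
        dpat = dcols.reshape(n, self.in_channels, kh, kw, ho, wo)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for u in range(kh):
            for v in range(kw):
                dxp[:, :, u : u + sh * ho : sh, v : v + sw * wo : sw] += dpat[
                    :, :, u, v
                ]
        return np.ascontiguousarray(
            dxp[:, :, ph : ph + x_shape[2], pw : pw + x_shape[3]]
        )


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels), "gamma")
        self.beta = Parameter(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.last_output_shape: tuple[int, ...] | None = None

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        self.gamma.value = np.ones(self.channels, dtype=DTYPE)
        self.beta.value = np.zeros(self.channels, dtype=DTYPE)
        self.running_mean[:] = 0.0
        self.running_var[:] = 1.0

    def parameters(self) -> Iterator[Parameter]:
        yield self.gamma
        yield self.beta

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE), train)
        self.last_output_shape = y.shape
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, was_train = self._cache
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        if not was_train:
            return dy * g
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        mean_dy = dy.mean(axis=(0, 2, 3), keepdims=True)
        mean_dy_xhat = (dy * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (g * (dy - mean_dy - xhat * mean_dy_xhat)).astype(DTYPE)


class Phish(Module):
    """x * tanh(GELU(x)) as a parameter-free layer."""

    def __init__(self):
        self.last_output_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = np.asarray(x, dtype=DTYPE)
        y = phish_array(self._x).astype(DTYPE)
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * phish_grad_array(self._x)).astype(DTYPE)


class AdaptiveAvgPool2d(Module):
    """Global average pool to a 1x1 spatial map."""

    def __init__(self):
        self.last_output_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        y = x.mean(axis=(2, 3), keepdims=True).astype(DTYPE)
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy / (h * w), self._in_shape).astype(DTYPE)


class Flatten(Module):
    def __init__(self):
        self.last_output_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        y = x.reshape(x.shape[0], -1)
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Dropout(Module):
    """Inverted dropout; active only when train=True. Draws from a seedable rng."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self.last_output_shape: tuple[int, ...] | None = None

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.rate > 0.0:
            keep = 1.0 - self.rate
            self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
            y = x * self._mask
        else:
            self._mask = None
            y = np.asarray(x, dtype=DTYPE)
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Module):
    """Affine map y = x W^T + b, weight shape (out_features, in_features)."""

    def __init__(self, in_features: int, out_features: int):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(np.zeros((out_features, in_features)), "weight")
        self.bias = Parameter(np.zeros(out_features), "bias")
        self.last_output_shape: tuple[int, ...] | None = None

    def init(self, rng: np.random.Generator) -> None:
        std = math.sqrt(2.0 / self.in_features)
        self.weight.value = rng.normal(0.0, std, self.weight.value.shape).astype(DTYPE)
        self.bias.value = np.zeros(self.out_features, dtype=DTYPE)

    def parameters(self) -> Iterator[Parameter]:
        yield self.weight
        yield self.bias

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = np.ascontiguousarray(x, dtype=DTYPE)
        y = self._x @ self.weight.value.T + self.bias.value
        self.last_output_shape = y.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Sequential(Module):
    def __init__(self, layers: Sequence[Module], names: Sequence[str] | None = None):
        self.layers = list(layers)
        self.names = list(names) if names is not None else [
            type(l).__name__ for l in self.layers
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> Iterator[Parameter]:
        for layer in self.layers:
            yield from layer.parameters()

    def modules(self) -> Iterator[Module]:
        yield self
        for layer in self.layers:
            yield from layer.modules()

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)


class Residual(Module):
    """y = x + body(x); identity skip, no projection, no post-activation."""

    def __init__(self, body: Module):
        self.body = body
        self.last_output_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.body.forward(x, train=train)
        if y.shape != x.shape:
            raise ValueError(
                f"residual body changed shape {x.shape} -> {y.shape}; skip is ill-typed"
            )
        out = x + y
        self.last_output_shape = out.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)

    def parameters(self) -> Iterator[Parameter]:
        yield from self.body.parameters()

    def modules(self) -> Iterator[Module]:
        yield self
        yield from self.body.modules()

    def init(self, rng: np.random.Generator) -> None:
        self.body.init(rng)


def zero_grads(module: Module) -> None:
    for p in module.parameters():
        p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float((logsumexp - z[np.arange(n), labels]).mean())
    p = softmax(logits)
    p[np.arange(n), labels] -= 1.0
    return loss, (p / n).astype(DTYPE)


class Adam:
    """Adam optimizer with the conventional defaults (0.9, 0.999, 1e-8)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                DTYPE
            )
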