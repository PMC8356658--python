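"""Minimal NumPy neural-network layer library (NHWC, float32 by default).

Feature maps are (N, H, W, C) arrays — channels last, matching the
H×W×C convention the architecture tables use.  Every layer is a
:class:`Module` with an explicit ``forward``/``backward`` pair; no
computation graph is built.  ``forward(x, training=True)`` caches whatever
the matching ``backward(grad)`` needs.

Channels-last keeps the arithmetic BLAS-friendly: a 1×1 convolution is one
contiguous GEMM of shape (N·H·W, Cin) × (Cin, Cout); k×k convolutions are
one GEMM per kernel offset; depthwise convolutions are fused
shift-multiply-adds broadcasting over the channel axis.

Spatial "same" padding follows the floor convention
``out = floor((H + 2*(k//2) - k)/s) + 1`` (zero padding), so stride 1
preserves H×W and stride 2 produces ceil(H/2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU6",
    "Identity",
    "Linear",
    "Dropout2d",
    "GlobalAvgPool",
]


class Parameter:
    """A learnable array with an accumulated gradient."""

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class; subclasses register Parameters / sub-Modules as attributes."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                # lists of modules occur e.g. in per-group filter banks
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def named_modules(self, prefix: str = ""):
        yield prefix or self.__class__.__name__.lower(), self
        for name, value in vars(self).items():
            sub = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Module):
                yield from value.named_modules(sub)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{sub}[{i}]")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator,
             dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(dtype)


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


class Conv2d(Module):
    """Dense 2-D convolution, zero "same" padding, stride 1 or 2.

    Weights are stored (k, k, Cin, Cout); the kernel is applied as k·k GEMMs
    of shape (N·Ho·Wo, Cin) × (Cin, Cout), one per offset.  Carries a bias by
    default (see the counting conventions in the methods note).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 1,
                 stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if out_channels <= 0:
            raise ValueError(f"non-positive filter count {out_channels}")
        if kernel % 2 == 0:
            raise ValueError(f"even kernel size {kernel} unsupported")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_he_init((kernel, kernel, in_channels, out_channels),
                                         fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._cache = None

    def out_shape(self, shape):
        h, w, c = shape
        p = self.kernel // 2
        s = self.stride
        ho = (h + 2 * p - self.kernel) // s + 1
        wo = (w + 2 * p - self.kernel) // s + 1
        return (ho, wo, self.out_channels)

    def macs(self, shape) -> int:
        ho, wo, _ = self.out_shape(shape)
        return ho * wo * self.kernel ** 2 * self.in_channels * self.out_channels

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[-1]}")
        n, h, w, c = x.shape
        k, s, p = self.kernel, self.stride, self.kernel // 2
        ho, wo, _ = self.out_shape((h, w, c))
        wts = self.weight.data.astype(x.dtype)
        if k == 1 and s == 1:
            cols = x.reshape(-1, c)
            y = cols @ wts[0, 0]
        else:
            # im2col: one GEMM of shape (N*Ho*Wo, k*k*Cin) x (k*k*Cin, Cout)
            xp = _pad_hw(x, p)
            sn, sh, sw, sc = xp.strides
            windows = np.lib.stride_tricks.as_strided(
                xp, (n, ho, wo, k, k, c), (sn, sh * s, sw * s, sh, sw, sc))
            cols = windows.reshape(n * ho * wo, k * k * c)
            y = cols @ wts.reshape(k * k * c, self.out_channels)
        y = y.reshape(n, ho, wo, self.out_channels)
        if self.bias is not None:
            y += self.bias.data.astype(x.dtype)
        if training:
            self._cache = (cols, (n, h, w, c))
        return y

    def backward(self, grad):
        cols, (n, h, w, c) = self._cache
        k, s, p = self.kernel, self.stride, self.kernel // 2
        ho, wo = grad.shape[1], grad.shape[2]
        wts = self.weight.data.astype(grad.dtype)
        gflat = grad.reshape(-1, self.out_channels)
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=0)
        if k == 1 and s == 1:
            self.weight.grad[0, 0] += cols.T @ gflat
            self._cache = None
            return (gflat @ wts[0, 0].T).reshape(n, h, w, c)
        self.weight.grad += (cols.T @ gflat).reshape(self.weight.grad.shape)
        gcols = gflat @ wts.reshape(k * k * c, self.out_channels).T
        gcols = gcols.reshape(n, ho, wo, k, k, c)
        # col2im: scatter-add each kernel offset back into the padded grid
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += gcols[:, :, :, i, j]
        self._cache = None
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class DepthwiseConv2d(Module):
    """k×k depthwise convolution, stride 1, zero "same" padding."""

    def __init__(self, channels: int, kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel = kernel
        self.weight = Parameter(_he_init((kernel, kernel, channels),
                                         kernel * kernel, rng))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None
        self._cache = None

    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        h, w, _ = shape
        return h * w * self.kernel ** 2 * self.channels

    def forward(self, x, training=False):
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"depthwise conv over {self.channels} channels got {x.shape[-1]}")
        n, h, w, c = x.shape
        k = self.kernel
        p = k // 2
        xp = _pad_hw(x, p)
        wts = self.weight.data.astype(x.dtype)
        y = wts[0, 0] * xp[:, :h, :w, :]
        for i in range(k):
            for j in range(k):
                if i or j:
                    y += wts[i, j] * xp[:, i:i + h, j:j + w, :]
        if self.bias is not None:
            y += self.bias.data.astype(x.dtype)
        if training:
            self._cache = (xp, (h, w))
        return y

    def backward(self, grad):
        xp, (h, w) = self._cache
        k = self.kernel
        p = k // 2
        gxp = np.zeros_like(xp)
        wts = self.weight.data.astype(grad.dtype)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i:i + h, j:j + w, :]
                self.weight.grad[i, j] += np.einsum("nhwc,nhwc->c", grad, sl)
                gxp[:, i:i + h, j:j + w, :] += wts[i, j] * grad
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 1, 2))
        self._cache = None
        return gxp[:, p:p + h, p:p + w, :]


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        return 0

    def forward(self, x, training=False):
        if training:
            flat = x.reshape(-1, x.shape[-1])
            mean = flat.mean(axis=0)
            var = np.square(flat).mean(axis=0) - np.square(mean)
            np.maximum(var, 0.0, out=var)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        mean = np.asarray(mean, dtype=x.dtype)
        # fused affine: y = x * (gamma * inv) + (beta - mean * gamma * inv)
        scale = self.gamma.data.astype(x.dtype) * inv
        y = x * scale
        y += self.beta.data.astype(x.dtype) - mean * scale
        if training:
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
        return y

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.size // grad.shape[-1]
        gflat = grad.reshape(-1, grad.shape[-1])
        xflat = xhat.reshape(-1, xhat.shape[-1])
        sum_g = gflat.sum(axis=0)
        sum_gx = np.einsum("nc,nc->c", gflat, xflat)
        self.gamma.grad += sum_gx
        self.beta.grad += sum_g
        g = self.gamma.data.astype(grad.dtype)
        gx = (grad - sum_g / m - xhat * (sum_gx / m)) * (g * inv)
        self._cache = None
        return gx


class ReLU6(Module):
    """Rectified linear activation clamped above at 6."""

    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        return 0

    def forward(self, x, training=False):
        y = np.clip(x, 0.0, 6.0)
        if training:
            self._mask = (x > 0.0) & (x < 6.0)
        return y

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class Identity(Module):
    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        return 0

    def forward(self, x, training=False):
        return x

    def backward(self, grad):
        return grad


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_he_init((out_features, in_features), in_features, rng))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))
        self._cache = None

    def macs(self, shape=None) -> int:
        return self.in_features * self.out_features

    def forward(self, x, training=False):
        if training:
            self._cache = x
        return x @ self.weight.data.T.astype(x.dtype) + self.bias.data.astype(x.dtype)

    def backward(self, grad):
        x = self._cache
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        self._cache = None
        return grad @ self.weight.data.astype(grad.dtype)


class Dropout2d(Module):
    """Channel dropout: zeroes whole feature maps with probability ``rate``."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        return 0

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        if x.ndim == 2:
            mask = (self.rng.random(x.shape) < keep) / keep
        else:
            mask = (self.rng.random((x.shape[0], 1, 1, x.shape[-1])) < keep) / keep
        self._mask = mask.astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class GlobalAvgPool(Module):
    """Average over the spatial grid: (N, H, W, C) -> (N, C)."""

    def out_shape(self, shape):
        return (shape[-1],)

    def macs(self, shape) -> int:
        return 0

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               self._shape).astype(grad.dtype).copy()
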