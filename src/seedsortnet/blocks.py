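"""Building blocks of the seed-sorting network.

Three bespoke blocks make up the backbone:

* :class:`RootModule` — a dual-branch stem.  A 3×3/16-filter convolution
  extracts shallow features at full resolution; one branch downsamples it
  with anti-aliased max pooling, the other with a strided 3×3 convolution
  followed by a 1×1 reduction back to 16 channels.  Concatenation yields 32
  channels at half resolution.
* :class:`ShieldBlock` — a dual-branch separable block.  The main branch is a
  sandglass: depthwise 3×3 (ReLU6) → pointwise reduction to ``round(C_out/t)``
  channels (linear) → pointwise expansion (ReLU6) → depthwise 3×3 (linear).
  The sub branch is a depthwise-separable 3×3 carrying ``ceil(C_out/r)``
  channels of the output, giving it a different receptive field.  The two are
  concatenated; when input and output widths match, an identity shortcut is
  added.
* :class:`MaxBlurPool` — anti-aliased 2× downsampling: dense (stride-1) 2×2
  max, a fixed normalized binomial blur, then stride-2 subsampling.

Every convolution is followed by batch normalization (and carries a bias —
see the counting conventions in the methods note).  The linear "activation"
is the absence of a nonlinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Identity,
    Module,
    ReLU6,
)

__all__ = [
    "ShieldBlockSpec",
    "MaxBlurPoolSpec",
    "ConvBNAct",
    "RootModule",
    "ShieldBlock",
    "MaxBlurPool",
    "shield_split",
]


def shield_split(out_channels: int, reduction_t: int, split_r: int = 6):
    """Channel bookkeeping of a Shield-block.

    Returns ``(hidden, main, sub)`` with ``hidden = round(out/t)`` (nearest),
    ``sub = ceil(out/r)`` and ``main = out - sub``, so the two branches
    concatenate exactly back to ``out_channels``.
    """
    hidden = int(round(out_channels / reduction_t))
    sub = math.ceil(out_channels / split_r)
    main = out_channels - sub
    if hidden < 1 or sub < 1 or main < 1:
        raise ValueError(
            f"degenerate split for out={out_channels}, t={reduction_t}, r={split_r}")
    return hidden, main, sub


@dataclass(frozen=True)
class ShieldBlockSpec:
    in_channels: int
    out_channels: int
    reduction_t: int
    split_r: int = 6
    use_shortcut: bool = False

    def __post_init__(self):
        if self.use_shortcut and self.in_channels != self.out_channels:
            raise ValueError(
                f"shortcut requires matching widths, got "
                f"{self.in_channels} -> {self.out_channels}")
        shield_split(self.out_channels, self.reduction_t, self.split_r)

    @property
    def hidden(self) -> int:
        return shield_split(self.out_channels, self.reduction_t, self.split_r)[0]

    @property
    def main(self) -> int:
        return shield_split(self.out_channels, self.reduction_t, self.split_r)[1]

    @property
    def sub(self) -> int:
        return shield_split(self.out_channels, self.reduction_t, self.split_r)[2]


# Normalized 3x3 binomial kernel: outer([1,2,1],[1,2,1])/16.
_BINOMIAL3 = (np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0).astype(np.float32)


@dataclass(frozen=True)
class MaxBlurPoolSpec:
    max_window: int = 2
    max_stride: int = 1
    blur_kernel: tuple = tuple(map(tuple, _BINOMIAL3))
    subsample_stride: int = 2

    def kernel_array(self) -> np.ndarray:
        k = np.asarray(self.blur_kernel, dtype=np.float32)
        if (k < 0).any() or not np.isclose(k.sum(), 1.0):
            raise ValueError("blur kernel must be nonnegative and sum to 1")
        return k


class ConvBNAct(Module):
    """Convolution → batch norm → activation ({relu6, linear})."""

    def __init__(self, in_channels: int, filters: int, kernel: int = 1,
                 stride: int = 1, depthwise: bool = False,
                 activation: str = "relu6",
                 rng: np.random.Generator | None = None):
        if kernel not in (1, 3, 7):
            raise ValueError(f"unsupported kernel {kernel}")
        if stride not in (1, 2):
            raise ValueError(f"unsupported stride {stride}")
        if activation not in ("relu6", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        if depthwise:
            if filters != in_channels:
                raise ValueError(
                    f"depthwise conv must keep width ({in_channels} != {filters})")
            if stride != 1:
                raise ValueError("depthwise convolutions here are stride 1")
            self.conv = DepthwiseConv2d(in_channels, kernel, rng=rng)
        else:
            self.conv = Conv2d(in_channels, filters, kernel, stride, rng=rng)
        self.bn = BatchNorm2d(filters)
        self.act = ReLU6() if activation == "relu6" else Identity()

    def out_shape(self, shape):
        return self.conv.out_shape(shape)

    def macs(self, shape) -> int:
        return self.conv.macs(shape)

    def forward(self, x, training=False):
        return self.act(self.bn(self.conv(x, training), training), training)

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(self.act.backward(grad)))


class MaxBlurPool(Module):
    """Anti-aliased downsampling: dense 2×2 max → binomial blur → stride 2.

    The dense max uses edge-replication on the right/bottom so stride-1 max
    keeps H×W; the blur uses reflect padding so constants are preserved
    exactly; subsampling takes every other row/column starting at the origin,
    producing ceil(H/2) × ceil(W/2).  No learnable parameters.
    """

    def __init__(self, spec: MaxBlurPoolSpec | None = None):
        self.spec = spec or MaxBlurPoolSpec()
        self.kernel = self.spec.kernel_array()
        if self.kernel.shape[0] % 2 == 0:
            raise ValueError("blur kernel must have odd size")
        self._cache = None

    def out_shape(self, shape):
        h, w, c = shape
        return (-(-h // 2), -(-w // 2), c)

    def macs(self, shape) -> int:
        return 0  # fixed kernel: no learnable parameters, excluded by convention

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h < 2 or w < 2:
            raise ValueError(f"spatial dims too small for pooling: {h}x{w}")
        # dense 2x2 max, stride 1, edge padding right/bottom
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)), mode="edge")
        m = np.maximum(
            np.maximum(xp[:, :h, :w], xp[:, 1:h + 1, :w]),
            np.maximum(xp[:, :h, 1:w + 1], xp[:, 1:h + 1, 1:w + 1]))
        # blur (reflect padding), evaluated only at the stride-2 sample points
        k = self.kernel.astype(x.dtype)
        ks = k.shape[0]
        p = ks // 2
        ho, wo = -(-h // 2), -(-w // 2)
        mp = np.pad(m, ((0, 0), (p, p), (p, p), (0, 0)), mode="reflect")
        y = np.zeros((n, ho, wo, c), dtype=x.dtype)
        for i in range(ks):
            for j in range(ks):
                y += k[i, j] * mp[:, i:i + h:2, j:j + w:2]
        if training:
            self._cache = (xp, m, (h, w))
        return y

    def backward(self, grad):
        xp, m, (h, w) = self._cache
        k = self.kernel.astype(grad.dtype)
        ks = k.shape[0]
        p = ks // 2
        n, c = grad.shape[0], grad.shape[-1]
        # blur backward through reflect padding (sample points only)
        gmp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for i in range(ks):
            for j in range(ks):
                gmp[:, i:i + h:2, j:j + w:2] += k[i, j] * grad
        gm = _fold_reflect(gmp, p, h, w)
        # dense-max backward: route to the first window position attaining the max
        gxp = np.zeros((n, h + 1, w + 1, c), dtype=grad.dtype)
        taken = np.zeros(m.shape, dtype=bool)
        for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
            view = xp[:, di:di + h, dj:dj + w]
            sel = (view == m) & ~taken
            gxp[:, di:di + h, dj:dj + w] += gm * sel
            taken |= sel
        gx = gxp[:, :h, :w].copy()
        gx[:, h - 1, :] += gxp[:, h, :w]
        gx[:, :, w - 1] += gxp[:, :h, w]
        gx[:, h - 1, w - 1] += gxp[:, h, w]
        self._cache = None
        return gx


def _fold_reflect(gp: np.ndarray, p: int, h: int, w: int) -> np.ndarray:
    """Adjoint of np.pad(..., mode='reflect') for pad width ``p`` (NHWC)."""
    g = gp[:, p:p + h, p:p + w].copy()
    for d in range(1, p + 1):
        g[:, d, :] += gp[:, p - d, p:p + w]
        g[:, h - 1 - d, :] += gp[:, p + h - 1 + d, p:p + w]
    for d in range(1, p + 1):
        col_l = gp[:, :, p - d]
        col_r = gp[:, :, p + w - 1 + d]
        g[:, :, d] += col_l[:, p:p + h]
        g[:, :, w - 1 - d] += col_r[:, p:p + h]
        for e in range(1, p + 1):
            g[:, e, d] += col_l[:, p - e]
            g[:, h - 1 - e, d] += col_l[:, p + h - 1 + e]
            g[:, e, w - 1 - d] += col_r[:, p - e]
            g[:, h - 1 - e, w - 1 - d] += col_r[:, p + h - 1 + e]
    return g


class RootModule(Module):
    """Dual-branch stem: 224×224×3 → 112×112×32 (for the default widths).

    ``branch_channels`` is the width of the strided 3×3 convolution in the
    convolutional branch; the following 1×1 reduces it to ``stem_channels``
    so the concatenation with the pooled branch doubles the stem width.
    Widths reconcile the published budgets; both are configurable.
    """

    def __init__(self, in_channels: int = 3, stem_channels: int = 16,
                 branch_channels: int = 52, out_channels: int | None = None,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.stem_channels = stem_channels
        self.branch_channels = branch_channels
        self.out_channels = out_channels or 2 * stem_channels
        branch_out = self.out_channels - stem_channels
        if branch_out < 1:
            raise ValueError(
                f"root output width {self.out_channels} must exceed the stem "
                f"width {stem_channels}")
        self.stem = ConvBNAct(in_channels, stem_channels, 3, 1, rng=rng)
        self.pool = MaxBlurPool()
        self.branch_conv = ConvBNAct(stem_channels, branch_channels, 3, 2, rng=rng)
        self.branch_reduce = ConvBNAct(branch_channels, branch_out, 1, 1, rng=rng)

    def out_shape(self, shape):
        h, w, c = shape
        return (-(-h // 2), -(-w // 2), self.out_channels)

    def forward(self, x, training=False):
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"stem expects {self.in_channels} input channels, got {x.shape[-1]}")
        s = self.stem(x, training)
        a = self.pool(s, training)
        b = self.branch_reduce(self.branch_conv(s, training), training)
        return np.concatenate([a, b], axis=-1)

    def backward(self, grad):
        c = self.stem_channels
        ga = self.pool.backward(grad[..., :c])
        gb = self.branch_conv.backward(self.branch_reduce.backward(grad[..., c:]))
        return self.stem.backward(ga + gb)


class ShieldBlock(Module):
    """Dual-branch separable block; see module docstring for the layout."""

    def __init__(self, spec: ShieldBlockSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        cin = spec.in_channels
        hidden, main, sub = shield_split(spec.out_channels, spec.reduction_t,
                                         spec.split_r)
        self.dw1 = ConvBNAct(cin, cin, 3, depthwise=True, rng=rng)
        self.pw_reduce = ConvBNAct(cin, hidden, 1, activation="linear", rng=rng)
        self.pw_expand = ConvBNAct(hidden, main, 1, rng=rng)
        self.dw2 = ConvBNAct(main, main, 3, depthwise=True,
                             activation="linear", rng=rng)
        self.sub_dw = ConvBNAct(cin, cin, 3, depthwise=True, rng=rng)
        self.sub_pw = ConvBNAct(cin, sub, 1, rng=rng)

    def out_shape(self, shape):
        return (shape[0], shape[1], self.spec.out_channels)

    def forward(self, x, training=False):
        if x.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"shield block expects {self.spec.in_channels} channels, "
                f"got {x.shape[-1]}")
        m = self.dw2(self.pw_expand(self.pw_reduce(self.dw1(x, training), training),
                                    training), training)
        s = self.sub_pw(self.sub_dw(x, training), training)
        y = np.concatenate([m, s], axis=-1)
        if self.spec.use_shortcut:
            y = y + x
        return y

    def backward(self, grad):
        main = self.spec.main
        gm = self.dw1.backward(self.pw_reduce.backward(
            self.pw_expand.backward(self.dw2.backward(grad[..., :main]))))
        gs = self.sub_dw.backward(self.sub_pw.backward(grad[..., main:]))
        gx = gm + gs
        if self.spec.use_shortcut:
            gx = gx + grad
        return gx
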