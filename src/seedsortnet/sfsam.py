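"""Sub-feature space attention (SFSAM).

The C input channels are split into g contiguous groups.  Each group i is
summarized by two channel-axis pooling maps — the per-position maximum and
mean over the group's channels — which a k×k convolution (2 → 1 channels,
with bias, one filter bank per group) turns into a single-channel score map.
A softmax over the H×W positions gates the scores into an attention map
M_i ∈ [0, 1] that sums to 1 over positions, and the group is re-weighted
residually:  F̂_i = M_i ⊗ F_i ⊕ F_i.  The groups are concatenated back in
order, so the module never changes the tensor shape.

The softmax-over-positions gating is one of two readings of the published
formula (the alternative, a per-element sigmoid, is available via
``gating="sigmoid"`` but is not the default); see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv2d, Module

__all__ = ["AttentionConfig", "split_groups", "channel_pool", "SFSAM"]


@dataclass(frozen=True)
class AttentionConfig:
    groups: int = 4
    kernel: int = 7
    per_group_filters: bool = True
    gating: str = "softmax"

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("attention kernel must be odd")
        if self.gating not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown gating {self.gating!r}")


def split_groups(x: np.ndarray, groups: int, site: str = "input") -> list[np.ndarray]:
    """Split (N, H, W, C) into ``groups`` contiguous channel slices."""
    c = x.shape[-1]
    if c % groups:
        raise ValueError(
            f"channel count {c} at site {site!r} is not divisible by g={groups}")
    return list(np.split(x, groups, axis=-1))


def channel_pool(x: np.ndarray) -> np.ndarray:
    """Channel-axis descriptors: stack of per-position max and mean.

    (N, H, W, C) -> (N, H, W, 2); channel 0 is the max, channel 1 the mean.
    """
    return np.stack([x.max(axis=-1), x.mean(axis=-1)], axis=-1)


class SFSAM(Module):
    """Grouped spatial attention over a feature map of ``channels`` width."""

    def __init__(self, channels: int, config: AttentionConfig | None = None,
                 rng: np.random.Generator | None = None, site: str = "sfsam"):
        config = config or AttentionConfig()
        if channels % config.groups:
            raise ValueError(
                f"SFSAM at site {site!r}: {channels} channels not divisible "
                f"by g={config.groups}")
        self.channels = channels
        self.config = config
        self.site = site
        n_filters = config.groups if config.per_group_filters else 1
        self.convs = [Conv2d(2, 1, config.kernel, 1, bias=True, rng=rng)
                      for _ in range(n_filters)]
        self._cache = None

    # -- profiling ---------------------------------------------------------
    def out_shape(self, shape):
        return shape

    def macs(self, shape) -> int:
        h, w, _ = shape
        # one 2->1 kxk convolution per group (conv arithmetic only)
        return self.config.groups * h * w * self.config.kernel ** 2 * 2

    # -- forward / backward ------------------------------------------------
    def _conv_for(self, i: int) -> Conv2d:
        return self.convs[i if self.config.per_group_filters else 0]

    def attention_map(self, descriptor: np.ndarray, group: int,
                      training: bool = False) -> np.ndarray:
        """k×k conv on a (N, H, W, 2) descriptor, then the gating. Returns (N, H, W)."""
        if descriptor.shape[-1] != 2:
            raise ValueError("descriptor must have exactly 2 channels")
        score = self._conv_for(group)(descriptor, training)[..., 0]
        if self.config.gating == "sigmoid":
            return 1.0 / (1.0 + np.exp(-score))
        n, h, w = score.shape
        flat = score.reshape(n, -1)
        e = np.exp(flat - flat.max(axis=1, keepdims=True))
        return (e / e.sum(axis=1, keepdims=True)).reshape(n, h, w)

    def forward(self, x, training=False):
        g = self.config.groups
        groups = split_groups(x, g, self.site)
        outs, cache = [], []
        for i, f in enumerate(groups):
            desc = channel_pool(f)
            m = self.attention_map(desc, i, training)
            outs.append(f * (1.0 + m[..., None]))
            if training:
                # stash the conv's own cache so a shared filter bank can be
                # replayed per group in backward
                cache.append((f, m, self._conv_for(i)._cache))
        if training:
            self._cache = cache
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        g = self.config.groups
        n = self.channels // g
        gx = []
        for i, (f, m, conv_cache) in enumerate(self._cache):
            gi = grad[..., i * n:(i + 1) * n]
            gf = gi * (1.0 + m[..., None])
            gm = (gi * f).sum(axis=-1)                      # (N, H, W)
            if self.config.gating == "sigmoid":
                gscore = gm * m * (1.0 - m)
            else:
                nb, h, w = gm.shape
                mf = m.reshape(nb, -1)
                gmf = gm.reshape(nb, -1)
                gscore = (mf * (gmf - (gmf * mf).sum(axis=1, keepdims=True))
                          ).reshape(nb, h, w)
            conv = self._conv_for(i)
            conv._cache = conv_cache
            gdesc = conv.backward(gscore[..., None])
            # channel_pool backward: max routes to argmax, mean spreads evenly
            amax = f.argmax(axis=-1)
            gmax = np.zeros_like(f)
            np.put_along_axis(gmax, amax[..., None], gdesc[..., 0:1], axis=-1)
            gf = gf + gmax + gdesc[..., 1:2] / f.shape[-1]
            gx.append(gf)
        self._cache = None
        return np.concatenate(gx, axis=-1)
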