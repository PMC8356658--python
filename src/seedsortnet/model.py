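"""Assembly of the full seed-sorting network.

The default topology (input 224×224×3, two classes):

======  ==================  ========  =====
stage   operator            t         C / R
======  ==================  ========  =====
1       root stem           —         32
2       shield ×2           2|6       64
3       attention (SFSAM)   —         64
4       max-blur pool       —         64
5       shield ×4           2|6       128
6       attention           —         128
7       max-blur pool       —         128
8       shield ×5           2|6       192
9       attention           —         192
10      max-blur pool       —         192
11      shield ×4           2|6       256
12      attention           —         256
13      max-blur pool       —         256
14      global avg pool     —         256
15      dropout + FC        —         2
======  ==================  ========  =====

The first shield block of each stage widens the features (t = 2, no
shortcut); the remaining blocks keep the width (t = 6) and carry an identity
shortcut.  15 shield blocks, 4 attention sites, 4 pooling stages in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blocks import MaxBlurPool, RootModule, ShieldBlock, ShieldBlockSpec
from .layers import Dropout2d, GlobalAvgPool, Linear, Module
from .sfsam import SFSAM, AttentionConfig

__all__ = [
    "StageEntry",
    "NetworkConfig",
    "default_stage_plan",
    "apply_width_multiplier",
    "build_network",
    "SeedSortNet",
]


@dataclass(frozen=True)
class StageEntry:
    operator: str                      # root|shield|sfsam|maxblurpool|globalavgpool|head
    out_channels: int
    repeats: int = 1
    t_first: int = 2
    t_rest: int = 6

    def __post_init__(self):
        if self.repeats < 1 or self.out_channels < 0:
            raise ValueError(f"invalid stage entry {self}")


def default_stage_plan(num_classes: int = 2) -> list[StageEntry]:
    """The published 15-stage layout (channels 32-64-128-192-256)."""
    plan = [StageEntry("root", 32)]
    for c, r in ((64, 2), (128, 4), (192, 5), (256, 4)):
        plan.append(StageEntry("shield", c, r))
        plan.append(StageEntry("sfsam", c))
        plan.append(StageEntry("maxblurpool", c))
    plan.append(StageEntry("globalavgpool", 256))
    plan.append(StageEntry("head", num_classes))
    return plan


@dataclass(frozen=True)
class NetworkConfig:
    width_multiplier: float = 1.0
    groups: int = 4
    use_sfsam: bool = True
    num_classes: int = 2
    dropout_rate: float = 0.2
    input_size: int = 224
    in_channels: int = 3
    split_r: int = 6
    stem_channels: int = 16
    root_branch_channels: int = 52
    attention_kernel: int = 7
    per_group_filters: bool = True
    gating: str = "softmax"
    stage_plan: tuple = field(default_factory=lambda: tuple(default_stage_plan()))

    def attention_config(self) -> AttentionConfig:
        return AttentionConfig(self.groups, self.attention_kernel,
                               self.per_group_filters, self.gating)


def _round_to_multiple(value: float, base: int) -> int:
    return max(base, int(round(value / base)) * base)


def apply_width_multiplier(plan: list[StageEntry] | tuple, m: float,
                           groups: int = 4) -> list[StageEntry]:
    """Scale all stage widths by ``m``, rounding to the nearest multiple of g.

    The head's class count is untouched; the global-average-pool width follows
    the last convolutional stage.
    """
    if not 0.0 < m <= 1.0:
        raise ValueError(f"width multiplier {m} outside (0, 1]")
    out: list[StageEntry] = []
    last = None
    for entry in plan:
        if entry.operator == "head":
            out.append(entry)
            continue
        base = max(groups, 1)
        if entry.out_channels * m < base:
            raise ValueError(f"width collapses below {base} at stage {entry}")
        c = _round_to_multiple(entry.out_channels * m, base)
        if entry.operator == "globalavgpool" and last is not None:
            c = last
        out.append(replace(entry, out_channels=c))
        last = c
    return out


class SeedSortNet(Module):
    """The full network: a callable (N, H, W, 3) → (N, num_classes) scorer."""

    def __init__(self, config: NetworkConfig | None = None,
                 rng: np.random.Generator | None = None):
        config = config or NetworkConfig()
        rng = rng or np.random.default_rng(0)
        self.config = config
        plan = list(config.stage_plan)
        if config.width_multiplier != 1.0:
            plan = apply_width_multiplier(plan, config.width_multiplier,
                                          config.groups)
        self.plan = plan
        att = config.attention_config()
        layers: list[tuple[str, Module]] = []
        cur = None
        for s, entry in enumerate(plan, start=1):
            name = f"stage{s}:{entry.operator}"
            if entry.operator == "root":
                # the 16-filter stem is a fixed property of the root module;
                # width scaling applies to the branch and stage widths only
                branch = _round_to_multiple(
                    config.root_branch_channels * config.width_multiplier, 4) \
                    if config.width_multiplier != 1.0 else config.root_branch_channels
                layers.append((name, RootModule(config.in_channels,
                                                config.stem_channels, branch,
                                                entry.out_channels, rng=rng)))
                cur = entry.out_channels
            elif entry.operator == "shield":
                for i in range(entry.repeats):
                    t = entry.t_first if i == 0 else entry.t_rest
                    shortcut = i > 0
                    spec = ShieldBlockSpec(cur, entry.out_channels, t,
                                           config.split_r, use_shortcut=shortcut)
                    layers.append((f"{name}[{i}]", ShieldBlock(spec, rng=rng)))
                    cur = entry.out_channels
            elif entry.operator == "sfsam":
                if not config.use_sfsam:
                    continue
                layers.append((name, SFSAM(cur, att, rng=rng, site=name)))
            elif entry.operator == "maxblurpool":
                layers.append((name, MaxBlurPool()))
            elif entry.operator == "globalavgpool":
                layers.append((name, GlobalAvgPool()))
            elif entry.operator == "head":
                layers.append((f"{name}:dropout",
                               Dropout2d(config.dropout_rate, rng=rng)))
                fc = Linear(cur, config.num_classes, rng=rng)
                # small-scale classifier init keeps the initial loss near ln(2)
                fc.weight.data = rng.normal(0.0, 0.01,
                                            fc.weight.data.shape).astype(np.float32)
                layers.append((f"{name}:fc", fc))
            else:
                raise ValueError(f"unknown operator {entry.operator!r}")
        self.layers = layers

    def parameters(self):
        return [p for _, layer in self.layers for p in layer.parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix or "seedsortnet", self
        for name, layer in self.layers:
            yield from layer.named_modules(name)

    def _batchnorms(self):
        return [m for _, m in self.named_modules() if hasattr(m, "running_mean")]

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 4 or x.shape[-1] != self.config.in_channels:
            raise ValueError(f"expected (N, H, W, {self.config.in_channels}) "
                             f"batch, got {x.shape}")
        if not np.isfinite(x).all():
            raise ValueError("non-finite values in input batch")
        for _, layer in self.layers:
            x = layer(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    # -- introspection -----------------------------------------------------
    def shape_trace(self, input_size: int | None = None) -> list[tuple[str, tuple]]:
        """Per-layer (name, output shape) without running any arithmetic."""
        size = input_size or self.config.input_size
        shape = (size, size, self.config.in_channels)
        trace = []
        for name, layer in self.layers:
            if isinstance(layer, Linear):
                shape = (layer.out_features,)
            else:
                shape = layer.out_shape(shape)
            trace.append((name, shape))
        return trace

    def summary(self) -> list[dict]:
        """JSON-ready architecture summary (operator, shape, params)."""
        out = []
        for (name, layer), (_, shape) in zip(self.layers, self.shape_trace()):
            out.append({"layer": name, "operator": type(layer).__name__,
                        "output_shape": list(shape),
                        "params": layer.param_count()})
        return out

    def save_weights(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        data = np.load(path)
        for i, p in enumerate(self.parameters()):
            p.data = data[f"p{i}"].copy()
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = data[f"rm{i}"].copy()
            bn.running_var = data[f"rv{i}"].copy()


def build_network(config: NetworkConfig | None = None,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> SeedSortNet:
    """Build a network from a configuration (validating SFSAM divisibility)."""
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    return SeedSortNet(config, rng=rng)
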