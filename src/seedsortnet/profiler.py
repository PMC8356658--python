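"""Learnable-parameter and multiply-accumulate profiling.

Counting conventions (recorded in every report):

* Parameters: convolution weights and biases, batch-norm affine pairs
  (2 per channel; running statistics are buffers, not parameters), attention
  filters and biases, and the classifier weights/bias.  The fixed blur kernel
  and all pooling contribute zero.
* MACs: one multiply-accumulate per kernel element per output position for
  convolutions (divided by the channel count for depthwise), ``in × out`` for
  the fully-connected head.  One MAC is reported as one FLOP, the convention
  the lightweight-CNN literature uses.  Normalization, activations, pooling,
  softmax and the element-wise attention arithmetic are excluded by default;
  ``count_elementwise=True`` adds one op per output element of those stages
  for the alternative reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import Linear
from .model import NetworkConfig, SeedSortNet, build_network

__all__ = [
    "ProfileReport",
    "count_params",
    "count_macs",
    "profile",
    "budget_reconciliation",
    "PRINTED_BUDGETS",
]

# Published budgets (millions of parameters, millions of MACs) per variant.
PRINTED_BUDGETS = {
    "default": (0.400, 512.06),
    "width_0.75": (0.23, 338.64),
    "no_sfsam": (0.399, 505.26),
    "g1": (0.399, 506.56),
    "g4": (0.400, 512.06),
    "g8": (0.402, 518.85),
    "g16": (0.405, 532.45),
}


@dataclass
class ProfileReport:
    total_params: int
    total_macs: int
    per_layer: list = field(default_factory=list)  # (name, operator, out_shape, params, macs)
    conventions: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.total_params == sum(r[3] for r in self.per_layer)
        assert self.total_macs == sum(r[4] for r in self.per_layer)

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def macs_m(self) -> float:
        return self.total_macs / 1e6

    def to_json(self) -> str:
        return json.dumps({
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "params_M": round(self.params_m, 6),
            "macs_M": round(self.macs_m, 6),
            "conventions": self.conventions,
            "per_layer": [
                {"layer": n, "operator": op, "output_shape": list(shape),
                 "params": p, "macs": m}
                for n, op, shape, p, m in self.per_layer],
        }, indent=2)

    def to_text(self) -> str:
        rows = [("layer", "operator", "output shape", "params", "MACs")]
        for n, op, shape, p, m in self.per_layer:
            rows.append((n, op, "x".join(map(str, shape)), str(p), str(m)))
        rows.append(("TOTAL", "", "", str(self.total_params), str(self.total_macs)))
        widths = [max(len(r[i]) for r in rows) for i in range(5)]
        return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths))
                         for r in rows)


def _elementwise_ops(layer, shape) -> int:
    """Per-output-element op count for the switchable convention."""
    if not hasattr(layer, "out_shape"):
        return 0
    out = layer.out_shape(shape)
    return int(np.prod(out))


def profile(network: SeedSortNet, input_size: int | None = None,
            count_elementwise: bool = False) -> ProfileReport:
    """Walk the network and count per-layer parameters and MACs."""
    size = input_size or network.config.input_size
    shape = (size, size, network.config.in_channels)
    per_layer = []
    for name, layer in network.layers:
        params = layer.param_count()
        if isinstance(layer, Linear):
            macs = layer.macs()
            out = (layer.out_features,)
        else:
            macs = layer_macs(layer, shape)
            out = layer.out_shape(shape)
        if count_elementwise and macs == 0:
            macs = _elementwise_ops(layer, shape)
        per_layer.append((name, type(layer).__name__, out, params, macs))
        shape = out
    report = ProfileReport(
        total_params=sum(r[3] for r in per_layer),
        total_macs=sum(r[4] for r in per_layer),
        per_layer=per_layer,
        conventions={
            "mac_equals_flop": True,
            "conv_bias_counted": True,
            "bn_affine_counted": True,
            "bn_running_stats_counted": False,
            "elementwise_ops_counted": count_elementwise,
            "input_size": size,
        },
    )
    return report


def layer_macs(layer, shape) -> int:
    """Conv/FC MACs of a composite layer at the given input shape."""
    from .blocks import ConvBNAct, MaxBlurPool, RootModule, ShieldBlock
    from .sfsam import SFSAM

    if isinstance(layer, ConvBNAct):
        return layer.macs(shape)
    if isinstance(layer, RootModule):
        s_shape = layer.stem.out_shape(shape)
        b_shape = layer.branch_conv.out_shape(s_shape)
        return (layer.stem.macs(shape) + layer.branch_conv.macs(s_shape)
                + layer.branch_reduce.macs(b_shape))
    if isinstance(layer, ShieldBlock):
        h, w, c = shape
        total = layer.dw1.macs(shape)
        total += layer.pw_reduce.macs((h, w, c))
        hidden = layer.spec.hidden
        total += layer.pw_expand.macs((h, w, hidden))
        main = layer.spec.main
        total += layer.dw2.macs((h, w, main))
        total += layer.sub_dw.macs(shape)
        total += layer.sub_pw.macs(shape)
        return total
    if isinstance(layer, (SFSAM, MaxBlurPool)):
        return layer.macs(shape)
    if hasattr(layer, "macs"):
        return layer.macs(shape)
    return 0


def count_params(network: SeedSortNet) -> ProfileReport:
    return profile(network)


def count_macs(network: SeedSortNet, input_size: int | None = None,
               count_elementwise: bool = False) -> ProfileReport:
    return profile(network, input_size, count_elementwise)


def _variant_configs() -> dict[str, NetworkConfig]:
    return {
        "default": NetworkConfig(),
        "no_sfsam": NetworkConfig(use_sfsam=False),
        "g1": NetworkConfig(groups=1),
        "g4": NetworkConfig(groups=4),
        "g8": NetworkConfig(groups=8),
        "g16": NetworkConfig(groups=16),
        "width_0.75": NetworkConfig(width_multiplier=0.75),
    }


def budget_reconciliation(variants: dict[str, NetworkConfig] | None = None,
                          seed: int = 0) -> list[dict]:
    """Profile every published variant and compare with the printed budgets."""
    variants = variants or _variant_configs()
    rows = []
    for name, cfg in variants.items():
        rep = profile(build_network(cfg, seed=seed))
        printed = PRINTED_BUDGETS.get(name)
        row = {
            "variant": name,
            "params": rep.total_params,
            "params_M": round(rep.params_m, 4),
            "macs": rep.total_macs,
            "macs_M": round(rep.macs_m, 2),
        }
        if printed:
            row["printed_params_M"] = printed[0]
            row["printed_macs_M"] = printed[1]
            row["params_diff_M"] = round(rep.params_m - printed[0], 4)
            row["macs_diff_M"] = round(rep.macs_m - printed[1], 2)
        rows.append(row)
    return rows
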