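"""Assembly of the LightMixer classifier and its parameter/MAC accounting.

The full network is

    stem -> DCWP -> LR -> head

with the DCWP and LR blocks individually switchable for ablation studies.
When DCWP is disabled but LR is kept, a pointwise 1x1 expansion adapter is
inserted after the stem so the LR block still sees its configured width;
the adapter's parameters are included in all reported totals.

Accounting comes in two independent flavours that the test-suite holds
equal: the closed-form count from each layer's :class:`~.blocks.LayerSpec`,
and the runtime enumeration of trainable values held by the weights.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import (
    BlockConfig,
    LayerSpec,
    build_dcwp,
    build_head,
    build_lr,
    build_stem,
    iter_specs,
)


@dataclass(frozen=True)
class ConvCostQuery:
    """Kernel side k, input channels U, output channels O for Eq.-style
    depthwise-vs-separable parameter comparisons."""

    k: int
    U: int
    O: int

    def __post_init__(self):
        if self.k < 1 or self.U < 1 or self.O < 1:
            raise ValueError("k, U and O must all be >= 1")


@dataclass
class ModelConfig:
    """Which blocks to build and how wide; ``seed`` fixes initialization."""

    num_classes: int = 10
    channels: int = 224
    use_dcwp: bool = True
    use_lr: bool = True
    block_cfg: BlockConfig = field(default_factory=BlockConfig)
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.channels != self.block_cfg.channels:
            self.block_cfg.channels = self.channels


def depthwise_vs_separable_ratio(q: ConvCostQuery) -> float:
    """Parameter ratio of depthwise-separable over depthwise convolution.

    (k^2*U + U*O) / (k^2*U) which simplifies to 1 + O/k^2 — independent of
    the input channel count U.
    """
    k2u = q.k * q.k * q.U
    return (k2u + q.U * q.O) / k2u


def assemble(cfg: ModelConfig) -> nn.Sequential:
    """Build the configured network with deterministic initialization.

    Weight init is Kaiming fan-in for convolutions and the affine head,
    zeros for biases, ones/zeros for batchnorm scale/shift, all drawn from
    a generator seeded by ``cfg.seed``; two assemblies with the same config
    are bit-identical.
    """
    in_channels = 3
    parts: list[nn.Module] = [build_stem(in_channels)]
    width = in_channels
    if cfg.use_dcwp:
        parts.append(build_dcwp(in_channels, cfg.channels, cfg.block_cfg))
        width = cfg.channels
    if cfg.use_lr:
        if width != cfg.channels:
            adapter = nn.Conv2d(width, cfg.channels, (1, 1), bias=True)
            adapter.spec = LayerSpec("conv", width, cfg.channels, (1, 1),
                                     has_bias=True)
            adapter.spec_name = "adapter.expand"
            parts.append(nn.Sequential([adapter], names=["adapter.expand"]))
            width = cfg.channels
        parts.append(build_lr(cfg.channels, cfg.block_cfg))
    parts.append(build_head(width, cfg.num_classes, cfg.block_cfg.dropout_rate))
    net = nn.Sequential(parts)
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, drop_seed = ss.spawn(2)
    net.init(np.random.default_rng(init_seed))
    reseed_dropout(net, drop_seed)
    net.config = cfg
    return net


def reseed_dropout(net: nn.Module, seed) -> None:
    """Reseed every dropout layer from one seed (stable module order)."""
    drops = [m for m in net.modules() if isinstance(m, nn.Dropout)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for d, s in zip(drops, ss.spawn(max(len(drops), 1))):
        d.reseed(int(s.generate_state(1)[0] % (2**31)))


def count_parameters(net: nn.Module) -> tuple[list[dict], int]:
    """Per-layer closed-form parameter table and its total.

    Each row is {"name", "kind", "params"}; the total is the plain sum.
    The runtime enumeration lives on ``net.num_parameters()`` and the two
    must agree for any assembled configuration.
    """
    rows = [
        {"name": name, "kind": spec.kind, "params": spec.param_count}
        for name, spec, _ in iter_specs(net)
    ]
    return rows, sum(r["params"] for r in rows)


def count_macs(
    net: nn.Module, input_size: tuple[int, int, int] = (3, 224, 224)
) -> dict:
    """Multiply-accumulate count of one forward pass at ``input_size``.

    Convolutions contribute output_positions * kh * kw * (Cin/groups) * Cout;
    the affine head contributes in*out; normalization, activations, pooling
    and biases are not counted.  "FLOPs" is reported as 2*MACs, the common
    convention in model-size tables.
    """
    c, h, w = input_size
    dummy = np.zeros((1, c, h, w), dtype=nn.DTYPE)
    net.forward(dummy, train=False)
    rows = []
    for name, spec, layer in iter_specs(net):
        shape = getattr(layer, "last_output_shape", None)
        positions = 1
        if shape is not None and len(shape) == 4:
            positions = int(shape[2] * shape[3])
        rows.append({"name": name, "kind": spec.kind, "macs": spec.macs(positions)})
    total = sum(r["macs"] for r in rows)
    return {"per_layer": rows, "macs": total, "flops": 2 * total}


def summarize(
    net: nn.Module, input_size: tuple[int, int, int] = (3, 224, 224)
) -> tuple[str, list[dict]]:
    """Architecture table: one row per layer with output shape, closed-form
    parameter count and MACs; returned both as text and as records."""
    c, h, w = input_size
    net.forward(np.zeros((1, c, h, w), dtype=nn.DTYPE), train=False)
    records = []
    for name, spec, layer in iter_specs(net):
        shape = getattr(layer, "last_output_shape", None)
        positions = 1
        if shape is not None and len(shape) == 4:
            positions = int(shape[2] * shape[3])
        records.append(
            {
                "name": name,
                "kind": spec.kind,
                "output_shape": list(shape[1:]) if shape is not None else [],
                "params": spec.param_count,
                "macs": spec.macs(positions),
            }
        )
    total_params = sum(r["params"] for r in records)
    total_macs = sum(r["macs"] for r in records)
    buf = io.StringIO()
    fmt = "{:<18} {:<15} {:<18} {:>12} {:>14}"
    print(fmt.format("Layer", "Type", "Output shape", "Params", "MACs"), file=buf)
    print("-" * 80, file=buf)
    for r in records:
        print(
            fmt.format(
                r["name"], r["kind"], "x".join(map(str, r["output_shape"])),
                f"{r['params']:,}", f"{r['macs']:,}",
            ),
            file=buf,
        )
    print("-" * 80, file=buf)
    print(f"Total params: {total_params:,}", file=buf)
    print(f"Total MACs:   {total_macs:,}  (FLOPs ~ {2 * total_macs:,})", file=buf)
    assert total_params == net.num_parameters(), "closed-form vs runtime mismatch"
    return buf.getvalue(), records


def predict_logits(
    net: nn.Module, inputs: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Forward in inference mode, batched; returns raw class scores."""
    outs = [
        net.forward(inputs[i : i + batch_size], train=False)
        for i in range(0, len(inputs), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def predict(net: nn.Module, inputs: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Predicted class ids (argmax of softmax scores)."""
    return predict_logits(net, inputs, batch_size).argmax(axis=1)
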