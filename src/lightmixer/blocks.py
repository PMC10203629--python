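"""Building blocks of the LightMixer network.

Four units are assembled here:

* the **stem** — a channelwise 3x3 convolution with stride 3 that brings a
  224x224 RGB image down to 75x75 with only 9*C + C trainable values
  (30 for RGB input);
* the **DCWP block** ("depth convolution with Phish") — pointwise channel
  expansion, a depthwise 3x3 filter, Phish, a 2x2 dense fusion convolution
  and batch normalization;
* the **LR block** ("light residual") — depthwise 9x9, Phish, batchnorm,
  pointwise 1x1, Phish, batchnorm, wrapped in an identity skip connection
  (optionally repeated in series, each repeat with its own skip);
* the **classifier head** — global average pool, flatten, dropout and an
  affine map to class scores (softmax is applied only in the loss and at
  prediction time).

Every constructed layer carries a :class:`LayerSpec` with a closed-form
trainable-parameter count, so the architecture table can be produced and
audited without touching the runtime weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from . import nn

_KINDS = {
    "conv",
    "depthwise_conv",
    "batchnorm",
    "phish",
    "pool",
    "flatten",
    "dropout",
    "linear",
}


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer with a closed-form parameter count."""

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple[int, int] = (0, 0)
    stride: tuple[int, int] = (1, 1)
    padding: tuple[int, int] = (0, 0)
    groups: int = 1
    has_bias: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "depthwise_conv" and not (
            self.groups == self.in_channels == self.out_channels
        ):
            raise ValueError("depthwise_conv requires groups == in == out channels")

    @property
    def param_count(self) -> int:
        """Trainable values implied by the spec alone (no weights needed)."""
        if self.kind in ("conv", "depthwise_conv"):
            kh, kw = self.kernel
            n = (kh * kw * self.in_channels // self.groups) * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "batchnorm":
            return 2 * self.out_channels
        if self.kind == "linear":
            return self.in_channels * self.out_channels + self.out_channels
        return 0

    def macs(self, output_positions: int) -> int:
        """Multiply-accumulates for one forward pass producing the given
        number of spatial output positions (1 for a linear layer)."""
        if self.kind in ("conv", "depthwise_conv"):
            kh, kw = self.kernel
            return (
                output_positions * kh * kw * (self.in_channels // self.groups)
                * self.out_channels
            )
        if self.kind == "linear":
            return self.in_channels * self.out_channels
        return 0


@dataclass
class BlockConfig:
    """Width and kernel configuration shared by the blocks.

    ``channels`` is the network width after the DCWP expansion (224 in the
    reference architecture).  ``lr_repeats`` controls how many residual
    bodies the LR block chains in series; the reference table lists one.
    """

    channels: int = 224
    dcwp_depthwise_kernel: tuple[int, int] = (3, 3)
    lr_depthwise_kernel: tuple[int, int] = (9, 9)
    lr_repeats: int = 1
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.lr_repeats < 1:
            raise ValueError("lr_repeats must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def _tag(layer: nn.Module, spec: LayerSpec, name: str) -> nn.Module:
    layer.spec = spec
    layer.spec_name = name
    return layer


def iter_specs(module: nn.Module) -> Iterator[tuple[str, LayerSpec, nn.Module]]:
    """Yield (name, LayerSpec, layer) for every tagged leaf layer, in order."""
    for m in module.modules():
        spec = getattr(m, "spec", None)
        if spec is not None:
            yield m.spec_name, spec, m


def build_stem(in_channels: int = 3) -> nn.Module:
    """Channelwise 3x3 stem convolution, stride 3, padding 1, with bias.

    Maps (N, C, 224, 224) to (N, C, 75, 75); the block itself is
    size-agnostic.  Parameter count is 9*C + C (30 for C=3).
    """
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    spec = LayerSpec(
        kind="depthwise_conv",
        in_channels=in_channels,
        out_channels=in_channels,
        kernel=(3, 3),
        stride=(3, 3),
        padding=(1, 1),
        groups=in_channels,
        has_bias=True,
    )
    conv = nn.Conv2d(
        in_channels, in_channels, (3, 3), stride=(3, 3), padding=(1, 1),
        groups=in_channels, bias=True,
    )
    return nn.Sequential([_tag(conv, spec, "stem.conv")], names=["stem.conv"])


def build_dcwp(
    in_channels: int = 3, channels: int = 224, cfg: BlockConfig | None = None
) -> nn.Module:
    """DCWP block: 1x1 expansion -> depthwise 3x3 -> Phish -> 2x2 fusion -> BN.

    The 2x2 fusion convolution has no padding and therefore shrinks the map
    by one pixel per axis (75 -> 74 at the reference resolution).  The
    depthwise filter keeps "same" spatial size and carries no bias.
    """
    cfg = cfg or BlockConfig(channels=channels)
    if channels <= 0:
        raise ValueError("channels must be positive")
    kh, kw = cfg.dcwp_depthwise_kernel
    specs = [
        ("dcwp.expand", LayerSpec("conv", in_channels, channels, (1, 1),
                                  has_bias=True)),
        ("dcwp.depthwise", LayerSpec("depthwise_conv", channels, channels, (kh, kw),
                                     padding=(kh // 2, kw // 2), groups=channels)),
        ("dcwp.phish", LayerSpec("phish", channels, channels)),
        ("dcwp.fuse", LayerSpec("conv", channels, channels, (2, 2), has_bias=True)),
        ("dcwp.bn", LayerSpec("batchnorm", channels, channels)),
    ]
    layers = [
        nn.Conv2d(in_channels, channels, (1, 1), bias=True),
        nn.Conv2d(channels, channels, (kh, kw), padding=(kh // 2, kw // 2),
                  groups=channels, bias=False),
        nn.Phish(),
        nn.Conv2d(channels, channels, (2, 2), bias=True),
        nn.BatchNorm2d(channels),
    ]
    for (name, spec), layer in zip(specs, layers):
        _tag(layer, spec, name)
    return nn.Sequential(layers, names=[n for n, _ in specs])


def _lr_body(channels: int, cfg: BlockConfig, idx: int) -> nn.Sequential:
    kh, kw = cfg.lr_depthwise_kernel
    p = f"lr{idx}"
    specs = [
        (f"{p}.depthwise", LayerSpec("depthwise_conv", channels, channels, (kh, kw),
                                     padding=(kh // 2, kw // 2), groups=channels,
                                     has_bias=True)),
        (f"{p}.phish1", LayerSpec("phish", channels, channels)),
        (f"{p}.bn1", LayerSpec("batchnorm", channels, channels)),
        (f"{p}.pointwise", LayerSpec("conv", channels, channels, (1, 1),
                                     has_bias=True)),
        (f"{p}.phish2", LayerSpec("phish", channels, channels)),
        (f"{p}.bn2", LayerSpec("batchnorm", channels, channels)),
    ]
    layers = [
        nn.Conv2d(channels, channels, (kh, kw), padding=(kh // 2, kw // 2),
                  groups=channels, bias=True),
        nn.Phish(),
        nn.BatchNorm2d(channels),
        nn.Conv2d(channels, channels, (1, 1), bias=True),
        nn.Phish(),
        nn.BatchNorm2d(channels),
    ]
    for (name, spec), layer in zip(specs, layers):
        _tag(layer, spec, name)
    return nn.Sequential(layers, names=[n for n, _ in specs])


def build_lr(channels: int = 224, cfg: BlockConfig | None = None) -> nn.Module:
    """LR block: ``lr_repeats`` residual units in series.

    Each unit runs depthwise 9x9 (same padding, bias) -> Phish -> batchnorm
    -> pointwise 1x1 (bias) -> Phish -> batchnorm, and adds the unit input
    back through an identity skip.  Spatial shape and channel count are
    preserved, so the skip is always well-typed.
    """
    cfg = cfg or BlockConfig(channels=channels)
    if channels <= 0:
        raise ValueError("channels must be positive")
    units = [nn.Residual(_lr_body(channels, cfg, i)) for i in range(cfg.lr_repeats)]
    return nn.Sequential(units, names=[f"lr{i}" for i in range(cfg.lr_repeats)])


def build_head(
    channels: int = 224, num_classes: int = 10, dropout_rate: float = 0.2
) -> nn.Module:
    """Classifier head: global average pool -> flatten -> dropout -> affine.

    Returns raw class scores; softmax lives in the loss and in prediction.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    specs = [
        ("head.pool", LayerSpec("pool", channels, channels)),
        ("head.flatten", LayerSpec("flatten", channels, channels)),
        ("head.dropout", LayerSpec("dropout", channels, channels)),
        ("head.linear", LayerSpec("linear", channels, num_classes)),
    ]
    layers = [
        nn.AdaptiveAvgPool2d(),
        nn.Flatten(),
        nn.Dropout(dropout_rate),
        nn.Linear(channels, num_classes),
    ]
    for (name, spec), layer in zip(specs, layers):
        _tag(layer, spec, name)
    return nn.Sequential(layers, names=[n for n, _ in specs])
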