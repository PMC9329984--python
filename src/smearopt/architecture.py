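"""CBD-parameterized CNN architecture plans.

The network is three convolutional blocks of ``cbd`` basic blocks each
(convolution + batch norm + ReLU), so the total number of convolution
layers is ``3 * cbd``.  Filter counts per block are proportional to
``1 / cbd`` (``round(base_filters * 2**(b-1) / cbd)``) so deeper variants
keep a comparable parameter budget, and convolutions are padded to
preserve spatial size.  Block 1 is followed by a 2x2 max pool, block 2 by
a 2x2 average pool, and block 3 by global average pooling feeding a
dropout + fully-connected + softmax head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ArchitectureConfig",
    "LayerSpec",
    "LayerPlan",
    "build_architecture",
    "count_layers",
    "count_trainable_parameters",
]

LAYER_KINDS = frozenset(
    {
        "convolution",
        "batch_norm",
        "relu",
        "max_pool",
        "average_pool",
        "global_average_pool",
        "dropout",
        "fully_connected",
        "softmax",
    }
)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Knobs of the block-structured classifier network."""

    cbd: int = 2
    base_filters: int = 32
    input_height: int = 64
    input_width: int = 64
    input_channels: int = 3
    num_classes: int = 2
    kernel_size: int = 3
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.cbd <= 6:
            raise ValueError(f"cbd must be in [1, 6], got {self.cbd}")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")
        for b in (1, 2, 3):
            if self.block_filters(b) < 1:
                raise ValueError(
                    f"block {b} filter count rounds below 1 for cbd={self.cbd}"
                )

    def block_filters(self, block: int) -> int:
        """Filters in block ``block`` (1-based): round(base * 2^(b-1) / cbd)."""
        return int(round(self.base_filters * 2 ** (block - 1) / self.cbd))


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class LayerPlan:
    """Ordered layer descriptors plus the input shape they assume."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]  # (channels, height, width)
    num_classes: int

    def to_listing(self) -> list[dict]:
        return [{"kind": l.kind, **l.attrs} for l in self.layers]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_listing(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_listing(), indent=2)


def build_architecture(config: ArchitectureConfig) -> LayerPlan:
    """Expand an :class:`ArchitectureConfig` into the full layer sequence."""
    layers: list[LayerSpec] = []
    in_ch = config.input_channels
    pad = config.kernel_size // 2  # preserves spatial size at stride 1

    pools = {1: "max_pool", 2: "average_pool"}
    for block in (1, 2, 3):
        filters = config.block_filters(block)
        for _ in range(config.cbd):
            layers.append(
                LayerSpec(
                    "convolution",
                    {
                        "filters": filters,
                        "in_channels": in_ch,
                        "kernel": config.kernel_size,
                        "stride": 1,
                        "padding": pad,
                    },
                )
            )
            layers.append(LayerSpec("batch_norm", {"channels": filters}))
            layers.append(LayerSpec("relu", {}))
            in_ch = filters
        if block in pools:
            layers.append(LayerSpec(pools[block], {"size": 2, "stride": 2}))
    layers.append(LayerSpec("global_average_pool", {}))
    layers.append(LayerSpec("dropout", {"p": config.dropout_p}))
    layers.append(
        LayerSpec(
            "fully_connected",
            {"in_features": in_ch, "out_features": config.num_classes},
        )
    )
    layers.append(LayerSpec("softmax", {}))
    return LayerPlan(
        layers=tuple(layers),
        input_shape=(config.input_channels, config.input_height, config.input_width),
        num_classes=config.num_classes,
    )


def count_layers(plan: LayerPlan, kind: str) -> int:
    """Number of layers of ``kind`` in the plan."""
    if kind not in LAYER_KINDS:
        raise ValueError(f"unknown layer kind {kind!r}")
    return sum(1 for l in plan.layers if l.kind == kind)


def count_trainable_parameters(plan: LayerPlan) -> int:
    """Total weights + biases using the standard conv/BN/FC formulas."""
    total = 0
    for l in plan.layers:
        if l.kind == "convolution":
            k = l.attrs["kernel"]
            total += k * k * l.attrs["in_channels"] * l.attrs["filters"]
            total += l.attrs["filters"]
        elif l.kind == "batch_norm":
            total += 2 * l.attrs["channels"]  # scale + shift
        elif l.kind == "fully_connected":
            total += l.attrs["in_features"] * l.attrs["out_features"]
            total += l.attrs["out_features"]
    return total
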