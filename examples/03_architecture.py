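"""Block-depth-parameterized CNN plans.

The network has three convolutional blocks of CBD basic blocks each
(conv + batch norm + ReLU), so the convolution count is 3*CBD, while the
filter counts scale as 1/CBD to keep the parameter budget comparable
across depths.
"""

from smearopt import (
    ArchitectureConfig,
    build_architecture,
    count_layers,
    count_trainable_parameters,
)

print(f"{'CBD':>3} {'conv':>5} {'filters/block':>15} {'parameters':>11}")
for cbd in range(1, 7):
    cfg = ArchitectureConfig(cbd=cbd)
    plan = build_architecture(cfg)
    filters = tuple(cfg.block_filters(b) for b in (1, 2, 3))
    print(f"{cbd:>3} {count_layers(plan, 'convolution'):>5} "
          f"{str(filters):>15} {count_trainable_parameters(plan):>11,}")

print()
print("deeper variants stack more 3x3 convolutions but narrow each layer,")
print("so the trainable-parameter count stays in the same range.")
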