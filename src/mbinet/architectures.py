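"""Declarative model construction: the MBINet classifier and its variants.

MBINet is an eight-layer network: seven operational (Self-ONN) layers plus
one MLP head.  All operational layers use 3x3 kernels, same padding and a
tanh activation; 2x2 stride-2 max pools follow layers 1, 3, 5 and 7, and a
final 3x3 stride-3 max pool precedes the flatten.  On a 224x224x3 input the
spatial trace is 224 -> 112 -> 56 -> 28 -> 14 -> 4, giving a 32 x 4 x 4 =
512-feature flatten feeding a 6-way SoftMax head.

The channel schedule of the default MBINet is (8, 8, 8, 8, 8, 16, 32).  The
architecture narration admits a second consistent reading with eight
operational stages; it is shipped as the ``enum8`` preset
(8, 8, 8, 8, 8, 16, 16, 32), which also flattens to 512.

Shallower variants (4 or 6 operational layers, optionally one extra hidden
dense layer, and vanilla-CNN twins with Q forced to 1) reuse the MBINet
schedule truncated to the stated depth; their exact widths were an open
design choice and are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, Flatten, MaxPool2d, OperationalConv2d, Sequential, Tanh

__all__ = [
    "LayerSpec",
    "ModelConfig",
    "ConfigError",
    "mbinet_config",
    "variant_config",
    "build_mbinet",
    "build_variant",
    "build_model",
    "count_parameters",
    "count_operational_layers",
    "trace_shapes",
    "MODEL_NAMES",
]


class ConfigError(ValueError):
    """A model configuration whose shape arithmetic is inconsistent."""


@dataclass
class LayerSpec:
    """One stage of a model: operational conv, max pool, flatten or dense."""

    kind: str  # operational | maxpool | flatten | dense
    out_channels: int | None = None
    kernel: tuple[int, int] = (3, 3)
    pool_size: int | None = None
    stride: int | None = None
    q_order: int | None = None
    units: int | None = None


@dataclass
class ModelConfig:
    """Declarative description of a classifier in this family."""

    name: str = "MBINet"
    input_size: tuple[int, int, int] = (224, 224, 3)  # (H, W, C)
    channel_schedule: tuple[int, ...] = (8, 8, 8, 8, 8, 16, 32)
    pool_after: tuple[int, ...] = (1, 3, 5, 7)  # 1-based operational layer indices
    pool_size: int = 2
    final_pool: tuple[int, int] = (3, 3)  # (size, stride) before flatten
    q_order: int = 3
    n_classes: int = 6
    hidden_dense: int | None = None  # width of the optional extra MLP layer
    declared_flatten: int | None = None  # cross-checked against the traced value

    def __post_init__(self):
        if any(c <= 0 for c in self.channel_schedule):
            raise ConfigError(f"channel schedule must be positive: {self.channel_schedule}")
        if self.q_order < 1:
            raise ConfigError(f"q_order must be >= 1, got {self.q_order}")

    def layer_specs(self) -> list[LayerSpec]:
        specs = []
        for i, c in enumerate(self.channel_schedule, start=1):
            specs.append(LayerSpec("operational", out_channels=c, q_order=self.q_order))
            if i in self.pool_after:
                specs.append(
                    LayerSpec("maxpool", pool_size=self.pool_size, stride=self.pool_size)
                )
        specs.append(
            LayerSpec("maxpool", pool_size=self.final_pool[0], stride=self.final_pool[1])
        )
        specs.append(LayerSpec("flatten"))
        if self.hidden_dense:
            specs.append(LayerSpec("dense", units=self.hidden_dense))
        specs.append(LayerSpec("dense", units=self.n_classes))
        return specs


def trace_shapes(config: ModelConfig) -> list[tuple[str, tuple]]:
    """Walk the shape arithmetic of a config; raises ConfigError naming the
    stage where the spatial extent collapses or the flatten disagrees with
    the declared length."""
    h, w, _ = config.input_size
    c = config.input_size[2]
    trace: list[tuple[str, tuple]] = [("input", (c, h, w))]
    flatten_len = None
    for spec in config.layer_specs():
        stage = f"{spec.kind}[{len(trace)}]"
        if spec.kind == "operational":
            c = spec.out_channels
        elif spec.kind == "maxpool":
            s = spec.stride
            h2 = (h - spec.pool_size) // s + 1
            w2 = (w - spec.pool_size) // s + 1
            if h2 < 1 or w2 < 1:
                raise ConfigError(
                    f"{config.name}: stage {stage} reduces {h}x{w} below 1x1"
                )
            h, w = h2, w2
        elif spec.kind == "flatten":
            flatten_len = c * h * w
            trace.append((stage, (flatten_len,)))
            continue
        elif spec.kind == "dense":
            trace.append((stage, (spec.units,)))
            continue
        trace.append((stage, (c, h, w)))
    if config.declared_flatten is not None and flatten_len != config.declared_flatten:
        raise ConfigError(
            f"{config.name}: flatten stage yields {flatten_len} features, "
            f"declared {config.declared_flatten}"
        )
    return trace


def flatten_length(config: ModelConfig) -> int:
    for stage, shape in trace_shapes(config):
        if stage.startswith("flatten"):
            return shape[0]
    raise ConfigError(f"{config.name}: no flatten stage")  # pragma: no cover


# ---------------------------------------------------------------------------
# model zoo
# ---------------------------------------------------------------------------

MODEL_NAMES = (
    "MBINet",
    "Self-ONN4L",
    "Self-ONN4L1DN",
    "Self-ONN6L",
    "Self-ONN6L1DN",
    "VanillaCNN6L",
    "VanillaCNN8L",
)

_SCHEDULES = {
    # (channel schedule, 2x2-pool positions)
    "mbinet": ((8, 8, 8, 8, 8, 16, 32), (1, 3, 5, 7)),
    "enum8": ((8, 8, 8, 8, 8, 16, 16, 32), (1, 3, 5, 7)),
    "6L": ((8, 8, 8, 8, 8, 16), (1, 3, 5)),
    "4L": ((8, 8, 8, 8), (1, 3)),
}


def _adapt_pools(input_hw: tuple[int, int], pools: tuple[int, ...],
                 final_pool=(3, 3)) -> tuple[int, ...]:
    """Keep 2x2 pool stages, in order, only while the spatial size entering
    the final pool stays >= 12.

    At the reference 224x224 input this selects the full canonical schedule
    (224 -> 112 -> 56 -> 28 -> 14 -> final pool -> 4); scaled-down inputs
    drop trailing pool stages instead of collapsing the flatten to a
    near-scalar summary.
    """
    h = min(input_hw)
    kept = []
    for p in pools:
        if h // 2 >= 12:
            kept.append(p)
            h //= 2
    return tuple(kept)


def mbinet_config(input_size=(224, 224, 3), q_order=3, preset="mbinet") -> ModelConfig:
    """Default MBINet configuration (declared 512 flatten on 224x224x3)."""
    schedule, pools = _SCHEDULES[preset]
    declared = 512 if input_size[:2] == (224, 224) else None
    return ModelConfig(
        name="MBINet" if preset == "mbinet" else f"MBINet[{preset}]",
        input_size=tuple(input_size),
        channel_schedule=schedule,
        pool_after=_adapt_pools(input_size[:2], pools),
        q_order=q_order,
        declared_flatten=declared,
    )


def variant_config(name: str, q_order: int | None = None,
                   input_size=(224, 224, 3), hidden_dense: int = 64) -> ModelConfig:
    """Configuration for a named model-zoo entry.

    The "1DN" suffix adds one hidden dense layer (default 64 units) before
    the class head; vanilla CNN variants are the same graphs with the
    polynomial order forced to 1.
    """
    if name not in MODEL_NAMES:
        raise KeyError(f"unknown model {name!r}; known: {MODEL_NAMES}")
    if name == "MBINet":
        return mbinet_config(input_size=input_size, q_order=3 if q_order is None else q_order)
    if name.startswith("Self-ONN"):
        depth = "4L" if "4L" in name else "6L"
        q = 3 if q_order is None else q_order
        hidden = hidden_dense if name.endswith("1DN") else None
    else:  # VanillaCNN6L / VanillaCNN8L: Q = 1 twins
        depth = "6L" if name == "VanillaCNN6L" else "mbinet"
        q = 1 if q_order is None else q_order
        hidden = None
    schedule, pools = _SCHEDULES[depth]
    return ModelConfig(
        name=name,
        input_size=tuple(input_size),
        channel_schedule=schedule,
        pool_after=_adapt_pools(input_size[:2], pools),
        q_order=q,
        hidden_dense=hidden,
    )


def build_model(config: ModelConfig, seed=None, dtype=np.float32) -> Sequential:
    """Materialize a config into a trainable layer stack (seeded init)."""
    trace_shapes(config)  # validate the arithmetic before allocating
    rng = np.random.default_rng(seed)
    layers = []
    c_in = config.input_size[2]
    flat = flatten_length(config)
    n_in = flat
    for spec in config.layer_specs():
        if spec.kind == "operational":
            layers.append(
                OperationalConv2d(c_in, spec.out_channels, kernel=spec.kernel[0],
                                  q_order=spec.q_order, rng=rng, dtype=dtype)
            )
            layers.append(Tanh())
            c_in = spec.out_channels
        elif spec.kind == "maxpool":
            layers.append(MaxPool2d(spec.pool_size, spec.stride))
        elif spec.kind == "flatten":
            layers.append(Flatten())
        elif spec.kind == "dense":
            layers.append(Dense(n_in, spec.units, rng=rng, dtype=dtype))
            if spec.units != config.n_classes:
                layers.append(Tanh())
            n_in = spec.units
    return Sequential(layers, name=config.name)


def build_mbinet(config: ModelConfig | None = None, seed=None, dtype=np.float32) -> Sequential:
    return build_model(config or mbinet_config(), seed=seed, dtype=dtype)


def build_variant(name: str, q_order: int | None = None, input_size=(224, 224, 3),
                  seed=None, dtype=np.float32) -> Sequential:
    return build_model(variant_config(name, q_order, input_size), seed=seed, dtype=dtype)


def count_parameters(model: Sequential) -> int:
    """Total trainable scalar count (weights plus biases)."""
    return model.num_parameters()


def count_operational_layers(model: Sequential) -> int:
    return sum(1 for layer in model.layers if isinstance(layer, OperationalConv2d))
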