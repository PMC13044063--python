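"""Full network assembly.

``ArchSpec`` declaratively describes a ResNet34-shaped backbone — a 7x7/2
stem with 3x3 max pooling, four stages of basic residual blocks with the
(3, 4, 6, 3) plan at (64, 128, 256, 512) channels, global average pooling and
a linear head — together with the toggles that define the model family:

* ``use_dwconv``  — the second 3x3 convolution of every basic block becomes a
  3x3 depthwise convolution (the lightweight variant);
* ``use_se``      — SE channel attention on the residual branch of every block;
* ``use_silu``    — SiLU activations instead of ReLU throughout;
* ``use_nested``  — the parameter-free nested inner skip in every block.

The full garlic-damage classifier enables all four; the plain baseline none.
The spec fully determines both the runnable network and its closed-form
parameter/MAC accounting (see :mod:`garlicnet.profiling`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .blocks import BlockSpec, ConvSpec, ResidualBlock, se_hidden
from .nn import (
    Activation,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    conv_output_hw,
)

__all__ = ["ArchSpec", "LayerPlanEntry", "GarlicNet", "build_model", "VARIANTS"]

VARIANTS = ("resnet34", "resnet34_dwconv", "dh_garlicnet", "custom")


@dataclass(frozen=True)
class ArchSpec:
    """Architecture description; defaults give the ResNet34 baseline."""

    num_classes: int = 1000
    use_dwconv: bool = False
    use_se: bool = False
    use_silu: bool = False
    use_nested: bool = False
    se_reduction: int = 16
    stage_blocks: tuple = (3, 4, 6, 3)
    stage_channels: tuple = (64, 128, 256, 512)

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if len(self.stage_blocks) != len(self.stage_channels):
            raise ValueError("stage_blocks and stage_channels length mismatch")

    @property
    def activation(self) -> str:
        return "silu" if self.use_silu else "relu"

    @property
    def stem_channels(self) -> int:
        return self.stage_channels[0]

    def stem_conv(self) -> ConvSpec:
        return ConvSpec(K=7, c_in=3, c_out=self.stem_channels, stride=2)

    def block_specs(self) -> list:
        """The residual block specs of all stages, in forward order."""
        specs = []
        c_prev = self.stem_channels
        for stage, (n_blocks, c) in enumerate(
            zip(self.stage_blocks, self.stage_channels)
        ):
            for b in range(n_blocks):
                first = b == 0
                stride = 2 if (first and stage > 0) else 1
                c_in = c_prev if first else c
                conv1 = ConvSpec(K=3, c_in=c_in, c_out=c, stride=stride)
                conv2 = ConvSpec(K=3, c_in=c, c_out=c, stride=1,
                                 depthwise=self.use_dwconv)
                projection = None
                if stride > 1 or c_in != c:
                    projection = ConvSpec(K=1, c_in=c_in, c_out=c,
                                          stride=stride)
                specs.append(
                    BlockSpec(
                        conv1=conv1,
                        conv2=conv2,
                        projection=projection,
                        use_se=self.use_se,
                        se_reduction=self.se_reduction,
                        activation=self.activation,
                        nested=self.use_nested,
                    )
                )
            c_prev = c
        return specs

    def layer_plan(self, input_hw: int = 224) -> list:
        """Enumerate every parameterised layer with its output spatial size.

        This is the single source both the closed-form profiler and the
        instantiated network share, so the two can be cross-checked exactly.
        """
        entries = []
        h = w = input_hw
        stem = self.stem_conv()
        h, w = conv_output_hw(h, w, 7, 2, 3)
        entries.append(LayerPlanEntry("stem.conv", "conv", conv=stem,
                                      out_h=h, out_w=w))
        entries.append(LayerPlanEntry("stem.bn", "bn",
                                      channels=self.stem_channels,
                                      out_h=h, out_w=w))
        h, w = conv_output_hw(h, w, 3, 2, 1)  # max pool
        for i, blk in enumerate(self.block_specs()):
            name = f"block{i}"
            bh, bw = conv_output_hw(h, w, 3, blk.conv1.stride, 1)
            entries.append(LayerPlanEntry(f"{name}.conv1", "conv",
                                          conv=blk.conv1, out_h=bh, out_w=bw))
            entries.append(LayerPlanEntry(f"{name}.bn1", "bn",
                                          channels=blk.conv1.c_out,
                                          out_h=bh, out_w=bw))
            entries.append(LayerPlanEntry(f"{name}.conv2", "conv",
                                          conv=blk.conv2, out_h=bh, out_w=bw))
            entries.append(LayerPlanEntry(f"{name}.bn2", "bn",
                                          channels=blk.conv2.c_out,
                                          out_h=bh, out_w=bw))
            if blk.projection is not None:
                entries.append(LayerPlanEntry(f"{name}.proj", "conv",
                                              conv=blk.projection,
                                              out_h=bh, out_w=bw))
                entries.append(LayerPlanEntry(f"{name}.bn_proj", "bn",
                                              channels=blk.projection.c_out,
                                              out_h=bh, out_w=bw))
            if blk.use_se:
                entries.append(LayerPlanEntry(f"{name}.se", "se",
                                              channels=blk.conv2.c_out,
                                              se_hidden=se_hidden(
                                                  blk.conv2.c_out,
                                                  blk.se_reduction),
                                              out_h=bh, out_w=bw))
            h, w = bh, bw
        entries.append(LayerPlanEntry("head.fc", "linear",
                                      in_features=self.stage_channels[-1],
                                      out_features=self.num_classes,
                                      out_h=1, out_w=1))
        return entries

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_blocks"] = list(self.stage_blocks)
        d["stage_channels"] = list(self.stage_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        d["stage_blocks"] = tuple(d.get("stage_blocks", (3, 4, 6, 3)))
        d["stage_channels"] = tuple(d.get("stage_channels",
                                          (64, 128, 256, 512)))
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ArchSpec":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)


@dataclass
class LayerPlanEntry:
    """One parameterised layer of the plan (conv / bn / linear / se)."""

    name: str
    kind: str
    conv: Optional[ConvSpec] = None
    channels: int = 0
    se_hidden: int = 0
    in_features: int = 0
    out_features: int = 0
    out_h: int = 0
    out_w: int = 0


class GarlicNet(Module):
    """Runnable network matching an :class:`ArchSpec`."""

    def __init__(self, spec: ArchSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        stem = spec.stem_conv()
        self.conv = Conv2d(stem.c_in, stem.c_out, stem.K, stem.stride,
                           pad=3, rng=rng)
        self.bn = BatchNorm2d(stem.c_out)
        self.act = Activation(spec.activation)
        self.pool = MaxPool2d(3, 2, 1)
        self.blocks = [ResidualBlock(b, rng=rng) for b in spec.block_specs()]
        self.gap = GlobalAvgPool()
        self.fc = Linear(spec.stage_channels[-1], spec.num_classes, rng=rng)
        self.last_features = None

    def forward_features(self, x):
        """Stem + all residual stages; caches the final feature map."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected a batch of shape (N, 3, H, W)")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError("spatial input size must be >= 32")
        x = self.pool(self.act(self.bn(self.conv(x))))
        for blk in self.blocks:
            x = blk(x)
        self.last_features = x
        return x

    def head_forward(self, feats):
        return self.fc(self.gap(feats))

    def forward(self, x):
        return self.head_forward(self.forward_features(x))

    def head_backward(self, grad_logits):
        """Gradient w.r.t. the final feature map (used by Grad-CAM)."""
        return self.gap.backward(self.fc.backward(grad_logits))

    def backward(self, grad_logits):
        g = self.head_backward(grad_logits)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.conv.backward(
            self.bn.backward(self.act.backward(self.pool.backward(g)))
        )

    # ---- checkpointing -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, blk in enumerate(self.blocks):
            for key, mod in _bn_modules(blk, f"blocks.{i}."):
                state[key + ".running_mean"] = mod.running_mean.copy()
                state[key + ".running_var"] = mod.running_var.copy()
        state["bn.running_mean"] = self.bn.running_mean.copy()
        state["bn.running_var"] = self.bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        self.bn.running_mean = state["bn.running_mean"].copy()
        self.bn.running_var = state["bn.running_var"].copy()
        for i, blk in enumerate(self.blocks):
            for key, mod in _bn_modules(blk, f"blocks.{i}."):
                mod.running_mean = state[key + ".running_mean"].copy()
                mod.running_var = state[key + ".running_var"].copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def _bn_modules(block: ResidualBlock, prefix: str):
    pairs = [(prefix + "bn1", block.bn1), (prefix + "bn2", block.bn2)]
    if block.proj is not None:
        pairs.append((prefix + "bn_proj", block.bn_proj))
    return pairs


def build_model(variant: str = "dh_garlicnet", num_classes: int = 3,
                seed: int = 0, **overrides) -> GarlicNet:
    """Construct a network by named variant.

    ``resnet34`` is the plain baseline (standard conv, ReLU, no SE, no
    nesting); ``resnet34_dwconv`` only swaps the second conv of every block
    for a depthwise one; ``dh_garlicnet`` enables depthwise conv, SE, SiLU and
    the nested skip; ``custom`` takes all toggles from ``overrides``.
    """
    spec = make_arch_spec(variant, num_classes=num_classes, **overrides)
    return GarlicNet(spec, rng=np.random.default_rng(seed))


def make_arch_spec(variant: str, num_classes: int = 3, **overrides) -> ArchSpec:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    base = {
        "resnet34": {},
        "resnet34_dwconv": {"use_dwconv": True},
        "dh_garlicnet": {"use_dwconv": True, "use_se": True,
                         "use_silu": True, "use_nested": True},
        "custom": {},
    }[variant]
    base.update(overrides)
    return ArchSpec(num_classes=num_classes, **base)
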