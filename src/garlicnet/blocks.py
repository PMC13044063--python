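"""Building blocks of the garlic-damage classifier.

This module holds the declarative convolution/block specs and their
closed-form parameter and multiply-accumulate (MAC) counts, plus the runnable
squeeze-and-excitation (SE) attention unit and the basic / nested residual
blocks the backbone is assembled from.

Counting conventions
--------------------
* a standard K x K convolution has ``K^2 * C_in * C_out`` weights and costs
  ``K^2 * C_in * C_out`` MACs per output pixel;
* a depthwise convolution keeps one kernel per input channel (no channel
  mixing): ``K^2 * C_in`` weights and ``K^2 * C_in`` MACs per output pixel;
* convolutions are bias-free (each is followed by batch norm, which carries
  the 2C affine parameters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import Activation, BatchNorm2d, Conv2d, Linear, Module
from .nn.functional import sigmoid

__all__ = [
    "ConvSpec",
    "BlockSpec",
    "conv_params",
    "conv_macs",
    "SEBlock",
    "ResidualBlock",
    "se_block",
    "residual_block",
]


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of one convolution layer.

    ``K`` is the (square) kernel size; ``depthwise`` marks a one-kernel-per-
    channel convolution, which forces ``c_out == c_in``.
    """

    K: int
    c_in: int
    c_out: int
    stride: int = 1
    depthwise: bool = False

    def __post_init__(self):
        if min(self.K, self.c_in, self.c_out, self.stride) < 1:
            raise ValueError("K, c_in, c_out and stride must all be >= 1")
        if self.depthwise and self.c_out != self.c_in:
            raise ValueError("depthwise convolution requires c_out == c_in")


def conv_params(spec: ConvSpec) -> int:
    """Weight count of one convolution (bias-free)."""
    k2 = spec.K * spec.K
    if spec.depthwise:
        return k2 * spec.c_in
    return k2 * spec.c_in * spec.c_out


def conv_macs(spec: ConvSpec, out_h: int, out_w: int) -> int:
    """Multiply-accumulates of one convolution at the given *output* size."""
    k2 = spec.K * spec.K
    if spec.depthwise:
        return k2 * spec.c_in * out_h * out_w
    return k2 * spec.c_in * spec.c_out * out_h * out_w


@dataclass(frozen=True)
class BlockSpec:
    """Spec of one residual block: two 3x3 convs, optional 1x1 projection
    shortcut, optional SE attention and optional parameter-free nested skip.

    The projection shortcut must be present exactly when the block changes
    resolution or channel count, and absent otherwise.
    """

    conv1: ConvSpec
    conv2: ConvSpec
    projection: Optional[ConvSpec] = None
    use_se: bool = False
    se_reduction: int = 16
    activation: str = "relu"
    nested: bool = False

    def __post_init__(self):
        if self.conv2.c_in != self.conv1.c_out:
            raise ValueError("conv1/conv2 channel chain inconsistent")
        needs_projection = self.conv1.stride > 1 or self.conv1.c_in != self.conv2.c_out
        if needs_projection != (self.projection is not None):
            raise ValueError(
                "projection shortcut required iff the block changes shape"
            )
        if self.projection is not None:
            p = self.projection
            if p.K != 1 or p.c_in != self.conv1.c_in or p.c_out != self.conv2.c_out:
                raise ValueError("projection must be 1x1 mapping block input "
                                 "channels to block output channels")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")

    @property
    def c_in(self) -> int:
        return self.conv1.c_in

    @property
    def c_out(self) -> int:
        return self.conv2.c_out

    @property
    def stride(self) -> int:
        return self.conv1.stride

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def se_hidden(c: int, reduction: int) -> int:
    """Bottleneck width of the SE gating MLP: floor(C / r), at least 1."""
    return max(c // reduction, 1)


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global-average-pools each channel, passes the channel descriptor through a
    bottleneck MLP (C -> C/r -> C) and rescales every channel by a sigmoid
    gate in (0, 1).  Shape is always preserved.
    """

    def __init__(self, c: int, reduction: int = 16, activation: str = "relu",
                 rng=None):
        super().__init__()
        h = se_hidden(c, reduction)
        self.c = c
        self.fc1 = Linear(c, h, rng=rng)
        self.act = Activation(activation)
        self.fc2 = Linear(h, c, rng=rng)
        self._cache = None

    def forward(self, x):
        n, c, hh, ww = x.shape
        s = x.mean(axis=(2, 3))
        z1 = self.fc1(s)
        self._z1 = z1  # activation input, needed for backward
        a = self.act.f(z1)
        g = sigmoid(self.fc2(a))
        self._cache = (x, g, (hh, ww))
        return x * g[:, :, None, None]

    def backward(self, gy):
        x, g, (hh, ww) = self._cache
        dx = gy * g[:, :, None, None]
        dg = (gy * x).sum(axis=(2, 3))
        dz2 = dg * g * (1.0 - g)
        da = self.fc2.backward(dz2)
        dz1 = da * self.act.df(self._z1)
        ds = self.fc1.backward(dz1)
        dx += ds[:, :, None, None] / (hh * ww)
        return dx


def se_block(x: np.ndarray, reduction: int = 16, activation: str = "relu",
             rng=None) -> np.ndarray:
    """Apply a freshly initialised SE block to a single feature map (C,H,W)."""
    mod = SEBlock(x.shape[0], reduction, activation, rng=rng)
    return mod(x[None])[0]


class ResidualBlock(Module):
    """Basic residual block, optionally depthwise / SE-gated / nested.

    The residual branch is ``BN(conv2(act(BN(conv1(x)))))``; the shortcut is
    the identity, or a 1x1 projection (with its own BN) when the block changes
    shape.  With ``nested=True`` an extra *parameter-free* identity skip is
    added around the first conv-BN-activation sub-unit; it is only active when
    that sub-unit preserves shape, so it never exists in projection blocks and
    never changes the parameter count.  SE, when enabled, rescales the branch
    output just before the residual summation.  The sum passes through the
    block activation.
    """

    def __init__(self, spec: BlockSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        c1, c2 = spec.conv1, spec.conv2
        self.conv1 = Conv2d(c1.c_in, c1.c_out, c1.K, c1.stride,
                            depthwise=c1.depthwise, rng=rng)
        self.bn1 = BatchNorm2d(c1.c_out)
        self.act1 = Activation(spec.activation)
        self.conv2 = Conv2d(c2.c_in, c2.c_out, c2.K, c2.stride,
                            depthwise=c2.depthwise, rng=rng)
        self.bn2 = BatchNorm2d(c2.c_out)
        # residual-friendly init: zero the branch's last BN scale so every
        # block starts as (a gated) identity, which speeds up short schedules
        self.bn2.gamma.data[...] = 0.0
        self.act_out = Activation(spec.activation)
        if spec.projection is not None:
            p = spec.projection
            self.proj = Conv2d(p.c_in, p.c_out, 1, p.stride, pad=0, rng=rng)
            self.bn_proj = BatchNorm2d(p.c_out)
        else:
            self.proj = None
        self.se = (SEBlock(c2.c_out, spec.se_reduction, rng=rng)
                   if spec.use_se else None)
        self._inner_skip = (spec.nested and c1.stride == 1
                            and c1.c_in == c1.c_out)

    def forward(self, x):
        if x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"block expects {self.spec.c_in} channels, got {x.shape[1]}"
            )
        u = self.act1(self.bn1(self.conv1(x)))
        if self._inner_skip:
            u = u + x
        branch = self.bn2(self.conv2(u))
        if self.se is not None:
            branch = self.se(branch)
        if self.proj is not None:
            shortcut = self.bn_proj(self.proj(x))
        else:
            shortcut = x
        return self.act_out(branch + shortcut)

    def backward(self, gy):
        g = self.act_out.backward(gy)
        # shortcut path
        if self.proj is not None:
            gx = self.proj.backward(self.bn_proj.backward(g))
        else:
            gx = g.copy()
        # branch path
        gb = g
        if self.se is not None:
            gb = self.se.backward(gb)
        gu = self.conv2.backward(self.bn2.backward(gb))
        if self._inner_skip:
            gx += gu
        gx += self.conv1.backward(self.bn1.backward(self.act1.backward(gu)))
        return gx


def residual_block(x: np.ndarray, spec: BlockSpec, rng=None) -> np.ndarray:
    """Run one freshly initialised residual block on a (C,H,W) feature map."""
    mod = ResidualBlock(spec, rng=rng)
    return mod(x[None])[0]
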