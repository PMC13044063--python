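"""Closed-form and empirical model profiling.

Parameter counts sum the convolution weight formulas plus the 2C affine
parameters of every batch-norm layer, the SE bottleneck MLPs when enabled and
the linear head (weights + bias).  The compute column counts multiply-
accumulate operations (MACs) of convolutions and linear layers only — batch
norm, pooling, activations and elementwise additions are excluded, the usual
profiler convention.  The two-decimal value is labelled ``gflops`` because
that is the vocabulary used for lightweight-CNN comparisons, but it is a MAC
count divided by 1e9.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .backbone import ArchSpec, GarlicNet, LayerPlanEntry, make_arch_spec
from .blocks import conv_macs, conv_params
from .nn import Conv2d

__all__ = ["ProfileReport", "profile", "profile_variant", "measured_macs",
           "measure_latency"]


@dataclass
class ProfileReport:
    params: int
    macs: int
    latency_ms: float | None = None

    @property
    def params_M(self) -> float:
        return round(self.params / 1e6, 1)

    @property
    def gflops(self) -> float:
        return round(self.macs / 1e9, 2)

    @property
    def weight_bytes(self) -> int:
        return 4 * self.params  # float32 storage

    @property
    def fps(self) -> float | None:
        if self.latency_ms is None:
            return None
        return 1000.0 / self.latency_ms

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "params_M": self.params_M,
            "macs": self.macs,
            "gflops": self.gflops,
            "weight_bytes": self.weight_bytes,
            "latency_ms": self.latency_ms,
            "fps": self.fps,
        }


def _entry_params(e: LayerPlanEntry) -> int:
    if e.kind == "conv":
        return conv_params(e.conv)
    if e.kind == "bn":
        return 2 * e.channels
    if e.kind == "linear":
        return e.in_features * e.out_features + e.out_features
    if e.kind == "se":
        c, h = e.channels, e.se_hidden
        return (c * h + h) + (h * c + c)
    raise ValueError(f"unknown layer kind {e.kind!r}")


def _entry_macs(e: LayerPlanEntry) -> int:
    if e.kind == "conv":
        return conv_macs(e.conv, e.out_h, e.out_w)
    if e.kind == "bn":
        return 0
    if e.kind == "linear":
        return e.in_features * e.out_features
    if e.kind == "se":
        return 2 * e.channels * e.se_hidden
    raise ValueError(f"unknown layer kind {e.kind!r}")


def profile(spec: ArchSpec, input_hw: int = 224) -> ProfileReport:
    """Closed-form parameter and per-image MAC totals for an architecture."""
    plan = spec.layer_plan(input_hw)
    params = sum(_entry_params(e) for e in plan)
    macs = sum(_entry_macs(e) for e in plan)
    return ProfileReport(params=params, macs=macs)


def profile_variant(variant: str, num_classes: int = 1000,
                    input_hw: int = 224, **overrides) -> ProfileReport:
    return profile(make_arch_spec(variant, num_classes=num_classes,
                                  **overrides), input_hw)


def measured_macs(net: GarlicNet, input_hw: int = 224) -> int:
    """Instrumented MAC count from an actual forward pass.

    Runs one image through the instantiated network and sums each conv
    layer's MACs at its *recorded* output size, plus linear and SE MLP MACs.
    Serves as the independent cross-check of :func:`profile`.
    """
    net.eval()
    net.forward(np.zeros((1, 3, input_hw, input_hw)))
    total = 0
    for mod in _walk(net):
        if isinstance(mod, Conv2d):
            total += mod.macs(*mod.last_output_hw)
    total += net.fc.weight.data.shape[0] * net.fc.weight.data.shape[1]
    for blk in net.blocks:
        if blk.se is not None:
            total += 2 * blk.se.fc1.weight.data.size
    return total


def _walk(module):
    yield module
    for sub in module.submodules():
        yield from _walk(sub)


def measure_latency(net: GarlicNet, input_hw: int = 224, reps: int = 10,
                    warmup: int = 2) -> tuple[float, float]:
    """Median wall-clock forward time for batch 1, in ms, and the implied FPS.

    Purely informational: wall-clock depends on hardware and BLAS and is
    never asserted against published timings.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    net.eval()
    x = np.zeros((1, 3, input_hw, input_hw))
    for _ in range(warmup):
        net.forward(x)
    times = []
    for _ in range(reps):
        t0 = time.perf_counter()
        net.forward(x)
        times.append((time.perf_counter() - t0) * 1000.0)
    ms = float(np.median(times))
    return ms, 1000.0 / ms
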