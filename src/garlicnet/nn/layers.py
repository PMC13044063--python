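"""Minimal trainable layer stack on NumPy arrays.

Layers follow the NCHW convention and implement explicit ``forward`` /
``backward`` passes: ``forward`` caches whatever the layer needs, ``backward``
takes the gradient w.r.t. the layer output, accumulates parameter gradients in
place and returns the gradient w.r.t. the layer input.  Modules are single-use
per forward pass (no weight sharing), which is all a feed-forward CNN needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .functional import get_activation

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool",
    "Activation",
    "Sequential",
]


class Parameter:
    """A trainable array with an accumulated gradient of the same shape."""

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: parameter discovery, train/eval mode, call syntax."""

    def __init__(self):
        self.training = True

    def submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
        for m in self.submodules():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        self.training = True
        for m in self.submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self.submodules():
            m.eval()
        return self

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _im2col(x: np.ndarray, K: int, stride: int, pad: int):
    """Unfold ``x`` (N,C,H,W) into windows (N, C, K, K, OH, OW)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (K, K), axis=(2, 3))  # N,C,H',W',K,K
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def _col2im(dcol: np.ndarray, x_shape, K: int, stride: int, pad: int):
    """Fold window gradients (N,C,K,K,OH,OW) back onto the input grid."""
    N, C, H, W = x_shape
    OH, OW = dcol.shape[4], dcol.shape[5]
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcol.dtype)
    for i in range(K):
        for j in range(K):
            dxp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += dcol[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv_output_hw(h: int, w: int, K: int, stride: int, pad: int):
    return (h + 2 * pad - K) // stride + 1, (w + 2 * pad - K) // stride + 1


class Conv2d(Module):
    """2-D convolution (cross-correlation), standard or depthwise, bias-free.

    A depthwise convolution keeps one K x K kernel per input channel and does
    no cross-channel mixing, so its parameter count is K^2 * C_in instead of
    K^2 * C_in * C_out.  Convolutions here carry no bias because every one is
    followed by a batch-norm layer that supplies the affine shift.
    """

    def __init__(self, c_in, c_out, K, stride=1, pad=None, depthwise=False, rng=None):
        super().__init__()
        if depthwise and c_out != c_in:
            raise ValueError("depthwise convolution requires C_out == C_in")
        self.c_in, self.c_out, self.K = c_in, c_out, K
        self.stride = stride
        self.pad = K // 2 if pad is None else pad
        self.depthwise = depthwise
        rng = rng or np.random.default_rng(0)
        fan_out = K * K * c_out if not depthwise else K * K
        std = np.sqrt(2.0 / fan_out)  # Kaiming fan-out for ReLU-family nets
        if depthwise:
            self.weight = Parameter(rng.normal(0.0, std, size=(c_in, K, K)))
        else:
            self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, K, K)))
        self._cache = None
        self.last_output_hw = None  # recorded at forward time, for profiling

    def forward(self, x):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        col = _im2col(x, self.K, self.stride, self.pad)  # N,C,K,K,OH,OW
        N, C, K, _, OH, OW = col.shape
        if self.depthwise:
            colf = col.reshape(N, C, K, K, OH * OW)
            y = np.einsum("ncklp,ckl->ncp", colf, self.weight.data).reshape(
                N, C, OH, OW
            )
        else:
            mat = col.reshape(N, C * K * K, OH * OW)
            w = self.weight.data.reshape(self.c_out, C * K * K)
            y = (w @ mat).reshape(N, self.c_out, OH, OW)
        self._cache = (x.shape, col)
        self.last_output_hw = (OH, OW)
        return y

    def backward(self, gy):
        x_shape, col = self._cache
        N, C, K, _, OH, OW = col.shape
        if self.depthwise:
            g = gy.reshape(N, C, OH * OW)
            colf = col.reshape(N, C, K, K, OH * OW)
            self.weight.grad += np.einsum("ncklp,ncp->ckl", colf, g)
            dcol = (
                self.weight.data[None, :, :, :, None] * g[:, :, None, None, :]
            ).reshape(N, C, K, K, OH, OW)
        else:
            gym = gy.reshape(N, self.c_out, OH * OW)
            mat = col.reshape(N, C * K * K, OH * OW)
            self.weight.grad += np.einsum("nop,nip->oi", gym, mat).reshape(
                self.weight.data.shape
            )
            w = self.weight.data.reshape(self.c_out, C * K * K)
            dcol = np.einsum("oi,nop->nip", w, gym).reshape(N, C, K, K, OH, OW)
        return _col2im(dcol, x_shape, K, self.stride, self.pad)

    def macs(self, out_h, out_w) -> int:
        """Multiply-accumulates for one sample at the given output size."""
        k2 = self.K * self.K
        if self.depthwise:
            return k2 * self.c_in * out_h * out_w
        return k2 * self.c_in * self.c_out * out_h * out_w


class BatchNorm2d(Module):
    """Per-channel batch normalisation with affine parameters (2C each)."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def forward(self, x):
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]

    def backward(self, gy):
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        g = gy * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * g - sum_g - xhat * sum_gx)


class Linear(Module):
    """Fully connected layer with bias."""

    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_out, n_in)))
        self.bias = Parameter(np.zeros(n_out))
        self._cache = None

    def forward(self, x):
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gy):
        x = self._cache
        self.weight.grad += gy.T @ x
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.data


class MaxPool2d(Module):
    """Max pooling; default 3x3 / stride 2 / pad 1 as in the ResNet stem."""

    def __init__(self, K=3, stride=2, pad=1):
        super().__init__()
        self.K, self.stride, self.pad = K, stride, pad
        self._cache = None

    def forward(self, x):
        K, s, p = self.K, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (K, K), axis=(2, 3))[:, :, ::s, ::s]
        N, C, OH, OW = win.shape[:4]
        flat = win.reshape(N, C, OH, OW, K * K)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, idx)
        return y

    def backward(self, gy):
        K, s, p = self.K, self.stride, self.pad
        x_shape, xp_shape, idx = self._cache
        N, C, OH, OW = idx.shape
        dxp = np.zeros((N * C, xp_shape[2] * xp_shape[3]), dtype=gy.dtype)
        oh = np.arange(OH)[:, None]
        ow = np.arange(OW)[None, :]
        rows = oh * s + idx // K  # padded coordinates
        cols = ow * s + idx % K
        lin = (rows * xp_shape[3] + cols).reshape(N * C, OH * OW)
        np.add.at(
            dxp,
            (np.arange(N * C)[:, None], lin),
            gy.reshape(N * C, OH * OW),
        )
        dxp = dxp.reshape(xp_shape)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Module):
    """Spatial mean over H,W: (N,C,H,W) -> (N,C)."""

    def __init__(self):
        super().__init__()
        self._hw = None

    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        H, W = self._hw
        return np.broadcast_to(gy[:, :, None, None], gy.shape + (H, W)).copy() / (H * W)


class Activation(Module):
    """Elementwise activation chosen by name from the activation registry."""

    def __init__(self, name: str):
        super().__init__()
        self.name = name
        self.f, self.df = get_activation(name)
        self._cache = None

    def forward(self, x):
        self._cache = x
        return self.f(x)

    def backward(self, gy):
        return gy * self.df(self._cache)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def backward(self, gy):
        for m in reversed(self.mods):
            gy = m.backward(gy)
        return gy
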