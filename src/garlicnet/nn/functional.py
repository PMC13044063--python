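"""Scalar nonlinearities and their derivatives.

Every activation is a pair ``(f, df)`` of vectorised NumPy callables so that
layer backward passes can be written as ``grad_in = grad_out * df(x)``.
All functions operate elementwise on arrays of any shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "silu", "ACTIVATIONS", "get_activation"]


def sigmoid(x):
    """Logistic function sigma(x) = 1 / (1 + exp(-x)), computed stably."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sigmoid_grad(x):
    s = sigmoid(x)
    return s * (1.0 - s)


def silu(x):
    """SiLU (swish) activation: x * sigma(x).

    Smooth and everywhere differentiable; tends to x for large positive
    inputs and to 0 for large negative inputs, giving a soft self-gating
    alternative to the hard cutoff of ReLU.
    """
    x = np.asarray(x, dtype=float)
    return x * sigmoid(x)


def _silu_grad(x):
    s = sigmoid(x)
    return s + x * s * (1.0 - s)


def _relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def _relu_grad(x):
    return (np.asarray(x) > 0).astype(float)


def _relu6(x):
    return np.clip(np.asarray(x, dtype=float), 0.0, 6.0)


def _relu6_grad(x):
    x = np.asarray(x)
    return ((x > 0) & (x < 6)).astype(float)


def _leaky_relu(x, slope=0.01):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, slope * x)


def _leaky_relu_grad(x, slope=0.01):
    return np.where(np.asarray(x) >= 0, 1.0, slope)


def _elu(x, alpha=1.0):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, alpha * np.expm1(x))


def _elu_grad(x, alpha=1.0):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0, alpha * np.exp(x))


def _softplus(x):
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def _mish(x):
    x = np.asarray(x, dtype=float)
    return x * np.tanh(_softplus(x))


def _mish_grad(x):
    x = np.asarray(x, dtype=float)
    sp = _softplus(x)
    t = np.tanh(sp)
    return t + x * (1.0 - t * t) * sigmoid(x)


_SQRT2 = np.sqrt(2.0)


def _gelu(x):
    from scipy.special import erf

    x = np.asarray(x, dtype=float)
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    from scipy.special import erf

    x = np.asarray(x, dtype=float)
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return cdf + x * pdf


def _hardsigmoid(x):
    return np.clip(np.asarray(x, dtype=float) / 6.0 + 0.5, 0.0, 1.0)


def _hardsigmoid_grad(x):
    x = np.asarray(x)
    return ((x > -3) & (x < 3)).astype(float) / 6.0


def _hardswish(x):
    x = np.asarray(x, dtype=float)
    return x * _hardsigmoid(x)


def _hardswish_grad(x):
    x = np.asarray(x, dtype=float)
    inner = ((x > -3) & (x < 3)).astype(float)
    return _hardsigmoid(x) + x * inner / 6.0


#: name -> (forward, derivative); the enum of selectable activations.
ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "silu": (silu, _silu_grad),
    "elu": (_elu, _elu_grad),
    "leaky_relu": (_leaky_relu, _leaky_relu_grad),
    "mish": (_mish, _mish_grad),
    "gelu": (_gelu, _gelu_grad),
    "relu6": (_relu6, _relu6_grad),
    "sigmoid": (sigmoid, _sigmoid_grad),
    "hardsigmoid": (_hardsigmoid, _hardsigmoid_grad),
    "hardswish": (_hardswish, _hardswish_grad),
}


def get_activation(name: str):
    """Return the ``(f, df)`` pair for ``name``; raise on unknown names."""
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
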