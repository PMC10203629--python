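"""Elementwise activation functions used by the LightMixer architecture.

The network's nonlinearity is Phish, the composition

    Phish(x) = x * tanh(GELU(x)),

built on the tanh approximation of the Gaussian error linear unit,

    GELU(x) = 0.5 * x * (1 + tanh(sqrt(2/pi) * (x + 0.044715 * x^3))).

Phish is smooth, nonnegative everywhere (x and tanh(GELU(x)) always share
sign), vanishes only at 0, behaves like the identity for large positive
inputs, and decays to 0 for large negative inputs.  All three functions are
total: finite inputs produce finite outputs and the output shape equals the
input shape.
"""

from __future__ import annotations

import numpy as np

from .nn import Phish as PhishLayer
from .nn import gelu_tanh_array, phish_array, phish_grad_array

__all__ = ["tanh", "gelu_tanh", "phish", "phish_grad", "PhishLayer"]


def tanh(x):
    """Hyperbolic tangent, (e^x - e^-x) / (e^x + e^-x), elementwise."""
    return np.tanh(np.asarray(x))


def gelu_tanh(x):
    """Tanh-approximation GELU, elementwise; accepts scalars or arrays."""
    return gelu_tanh_array(x)


def phish(x):
    """Phish activation x * tanh(gelu_tanh(x)), elementwise."""
    return phish_array(x)


def phish_grad(x):
    """Analytic first derivative of :func:`phish`; finite on all finite inputs."""
    return phish_grad_array(x)
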