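"""Array-or-Tensor dispatching math helpers.

Every function here accepts either a plain numpy array or an autodiff
:class:`~mgbind.nn.tensor.Tensor` and returns the same kind. Domain code
(attention, bilinear maps, losses) is written once against this surface
and is exercised both as plain numpy (unit tests, oracles) and inside the
trainable model.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "relu", "elu", "leaky_relu", "sigmoid", "tanh", "identity",
    "exp", "log", "absolute", "softmax", "concatenate", "get_activation",
]


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def relu(x):
    return x.relu() if _is_tensor(x) else np.maximum(x, 0.0)


def elu(x, alpha: float = 1.0):
    if _is_tensor(x):
        return x.elu(alpha)
    return np.where(x > 0, x, alpha * (np.exp(np.minimum(x, 0.0)) - 1.0))


def leaky_relu(x, slope: float = 0.2):
    if _is_tensor(x):
        return x.leaky_relu(slope)
    return np.where(x > 0, x, slope * x)


def sigmoid(x):
    if _is_tensor(x):
        return x.sigmoid()
    from .tensor import _stable_sigmoid

    return _stable_sigmoid(np.asarray(x, dtype=float))


def tanh(x):
    return x.tanh() if _is_tensor(x) else np.tanh(x)


def identity(x):
    return x


def exp(x):
    return x.exp() if _is_tensor(x) else np.exp(x)


def log(x):
    return x.log() if _is_tensor(x) else np.log(x)


def absolute(x):
    return x.abs() if _is_tensor(x) else np.abs(x)


def softmax(x, axis: int = -1):
    if _is_tensor(x):
        return x.softmax(axis=axis)
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(items, axis: int = -1):
    from .tensor import concat

    if any(_is_tensor(x) for x in items):
        return concat(items, axis=axis)
    return np.concatenate(items, axis=axis)


_ACTIVATIONS = {
    "relu": relu,
    "elu": elu,
    "leaky_relu": leaky_relu,
    "sigmoid": sigmoid,
    "tanh": tanh,
    "identity": identity,
    "linear": identity,
}


def get_activation(name):
    """Resolve an activation by name; callables pass through."""
    if callable(name):
        return name
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None
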