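"""Neural network building blocks on top of the autodiff Tensor.

Conventions: sequence inputs are (batch, positions, channels); parameter
initialisation is Glorot-uniform from an explicit numpy Generator so a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

__all__ = [
    "Module", "Parameter", "Linear", "Embedding", "Conv1d", "ConvTranspose1d",
    "LayerNorm", "BatchNorm1d", "MultiHeadSelfAttention", "masked_max",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # state also includes non-trainable buffers (batch-norm running stats)
    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            else:
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = getattr(obj, part) if not part.isdigit() else obj[int(part)]
                setattr(obj, attr, np.asarray(value, dtype=np.float64).copy())


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Lookup table; index 0 is reserved padding and always embeds to zero."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def forward(self, ids: np.ndarray):
        ids = np.asarray(ids, dtype=np.intp)
        out = self.weight[ids]
        pad_mask = (ids != 0).astype(np.float64)[..., None]
        return out * pad_mask


class Conv1d(Module):
    """1-D convolution over (batch, positions, channels), 'same' padding
    by default (odd kernels)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, pad: int | None = None):
        super().__init__()
        self.kernel = kernel
        self.pad = kernel // 2 if pad is None else pad
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.weight = Parameter(glorot(rng, fan_in, fan_out, (kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        b, t, _ = x.shape
        if self.pad:
            zeros = Tensor(np.zeros((b, self.pad, x.shape[2])))
            x = concat([zeros, x, zeros], axis=1)
        t_out = x.shape[1] - self.kernel + 1
        out = None
        for k in range(self.kernel):
            term = x[:, k:k + t_out, :] @ self.weight[k]
            out = term if out is None else out + term
        return out + self.bias


class ConvTranspose1d(Module):
    """Stride-1 transposed 1-D convolution: full correlation with the
    flipped kernel, trimmed back to the input length ('same' output)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.weight = Parameter(glorot(rng, fan_in, fan_out, (kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        b, t, _ = x.shape
        k = self.kernel
        zeros = Tensor(np.zeros((b, k - 1, x.shape[2])))
        xp = concat([zeros, x, zeros], axis=1)
        full_len = t + k - 1
        out = None
        for j in range(k):
            term = xp[:, j:j + full_len, :] @ self.weight[k - 1 - j]
            out = term if out is None else out + term
        lo = (k - 1) // 2
        return out[:, lo:lo + t, :] + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Channel-wise batch norm over (batch, positions, channels)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mean = x.data.mean(axis=(0, 1))
            var = x.data.var(axis=(0, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            mu = x.mean(axis=(0, 1), keepdims=True)
            centered = x - mu
            v = (centered**2.0).mean(axis=(0, 1), keepdims=True)
            return centered * (v + self.eps) ** (-0.5) * self.gamma + self.beta
        centered = x - self.running_mean
        return (centered * (self.running_var + self.eps) ** (-0.5) * self.gamma
                + self.beta)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with optional key padding mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x, mask: np.ndarray | None = None):
        b, t, _ = x.shape
        h, d = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, t, 3, h, d).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        if mask is not None:
            bias = (1.0 - np.asarray(mask, dtype=np.float64))[:, None, None, :]
            scores = scores + Tensor(-1e9 * bias)
        att = scores.softmax(axis=-1)
        self.last_attention = att.data
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(b, t, self.dim)
        return self.out(out)


def masked_max(x, mask: np.ndarray, axis: int = 1):
    """Max over ``axis`` restricted to positions where mask==1.

    ``mask`` is broadcast over trailing channel dims. Rows with an empty
    mask yield the max of -1e9 fill (never NaN).
    """
    mask = np.asarray(mask, dtype=np.float64)
    while mask.ndim < (x.ndim if isinstance(x, Tensor) else np.ndim(x)):
        mask = mask[..., None]
    fill = -1e9 * (1.0 - mask)
    return (x * mask + fill).max(axis=axis)
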