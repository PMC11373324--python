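"""Neural-network building blocks on top of the autodiff ``Tensor``.

Parameter containers follow the familiar module pattern: a ``Module`` owns
parameters and sub-modules as attributes, and ``named_parameters`` walks the
attribute tree in insertion order so checkpoints have stable, human-readable
keys.  Initialisation is always driven by an explicit ``numpy.random.Generator``
— there is no global RNG state anywhere in the package.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MLP",
    "ModuleList",
    "shifted_softplus",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item
            elif isinstance(value, dict):
                for k, item in value.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{k}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{k}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class ModuleList(Module):
    def __init__(self, modules):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Linear(Module):
    """Affine map ``x W + b`` with Glorot-uniform weights."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        limit = math.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        squeeze = False
        if x.ndim == 1:
            x = x.reshape((1, -1))
            squeeze = True
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        if squeeze:
            out = out.reshape((-1,))
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        self.weight = Parameter(rng.normal(0.0, scale, size=(num_embeddings, dim)))
        self.num_embeddings = num_embeddings

    def __call__(self, indices) -> Tensor:
        idx = np.asarray(indices, dtype=np.intp)
        if np.any(idx < 0) or np.any(idx >= self.num_embeddings):
            raise IndexError(
                f"embedding index out of range [0, {self.num_embeddings}): "
                f"min={idx.min()}, max={idx.max()}"
            )
        return self.weight.take_rows(idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


_LOG2 = math.log(2.0)


def shifted_softplus(x: Tensor) -> Tensor:
    """ln(0.5 e^x + 0.5) — the SchNet nonlinearity (zero at zero)."""
    return x.softplus() - _LOG2


class MLP(Module):
    """Feed-forward stack with a choice of nonlinearity between layers."""

    def __init__(self, dims, rng: np.random.Generator, activation: str = "relu"):
        self.layers = ModuleList([Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])])
        self.activation = activation

    def _act(self, x: Tensor) -> Tensor:
        if self.activation == "relu":
            return x.relu()
        if self.activation == "ssp":
            return shifted_softplus(x)
        if self.activation == "tanh":
            return x.tanh()
        raise ValueError(f"unknown activation {self.activation!r}")

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < n - 1:
                x = self._act(x)
        return x
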