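"""Small neural-network layer on top of the autodiff engine.

Modules hold :class:`~oncofuse._autodiff.Tensor` parameters; ``parameters()``
and ``named_parameters()`` walk attributes recursively, so composite models
(encoders inside a fusion network) serialize and optimize uniformly.  All
parameter initialisation draws from an explicit ``numpy.random.Generator`` —
there is no global random state anywhere in the package.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "Embedding",
    "Dropout",
    "Adam",
    "cosine_lr",
    "glorot_uniform",
    "sinusoidal_positions",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in=None, fan_out=None):
    fan_in = fan_in if fan_in is not None else shape[0]
    fan_out = fan_out if fan_out is not None else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class providing parameter traversal and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            value = np.asarray(state[name], dtype=np.float64)
            if value.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {value.shape} vs {p.data.shape}"
                )
            p.data = value.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias=True):
        self.weight = ad.parameter(glorot_uniform(rng, (n_in, n_out)))
        self.bias = ad.parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class Conv2d(Module):
    """Valid convolution, NHWC layout, square kernel."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 rng: np.random.Generator):
        k = int(kernel_size)
        fan_in = c_in * k * k
        self.weight = ad.parameter(
            glorot_uniform(rng, (c_in, k, k, c_out), fan_in=fan_in, fan_out=c_out)
        )
        self.bias = ad.parameter(np.zeros(c_out))
        self.stride = int(stride)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride)


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = ad.parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), (vocab_size, dim)))
        self.vocab_size = int(vocab_size)

    def __call__(self, tokens: np.ndarray) -> Tensor:
        tokens = np.asarray(tokens)
        bad = (tokens < 0) | (tokens >= self.vocab_size)
        if bad.any():
            pos = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(
                f"token {int(tokens[pos])} at position {pos} outside vocabulary "
                f"[0, {self.vocab_size})"
            )
        return ad.getitem(self.weight, tokens)


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)

    def __call__(self, x: Tensor, rng: np.random.Generator | None, active: bool) -> Tensor:
        if not active or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("active dropout requires a random generator")
        return ad.dropout(x, self.rate, rng)


def sinusoidal_positions(n_tokens: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional code, interleaved by frequency."""
    positions = np.arange(n_tokens)[:, None]
    i = np.arange(dim)[None, :]
    angle = positions / np.power(10000.0, (2 * (i // 2)) / dim)
    code = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return code


class Adam(Module):
    """Adam optimizer; the learning rate is mutable for scheduling."""

    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = float(beta1), float(beta2), float(eps)
        self.weight_decay = float(weight_decay)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self._t)
            v_hat = v / (1 - b2 ** self._t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``base_lr`` to 0 over ``total_epochs``."""
    if total_epochs <= 1:
        return base_lr
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * epoch / total_epochs))
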