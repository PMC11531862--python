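"""Minimal neural-network building blocks on top of :mod:`mtloc.autodiff`.

Provides parameter containers, affine layers, batch normalisation with
train/eval running statistics, and the Adam optimiser.  Initialisation is
Kaiming-style uniform with fan-in scaling, driven by an explicit
`numpy.random.Generator` so that model construction is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Linear", "BatchNorm1d", "MLP", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _params_of(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        seen: set[int] = set()
        for name, value in self.__dict__.items():
            yield from _named_params_of(value, f"{prefix}{name}", seen)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, mode: bool) -> None:
        self.training = mode
        for value in self.__dict__.values():
            for mod in _modules_of(value):
                mod._set_mode(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = {name: (holder, attr) for name, holder, attr in self._buffer_refs()}
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                own[name].data[...] = arr
            elif name in bufs:
                holder, attr = bufs[name]
                getattr(holder, attr)[...] = arr
            else:
                raise KeyError(f"unknown entry {name!r} in state dict")

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for name, holder, attr in self._buffer_refs():
            yield name, getattr(holder, attr)

    def _buffer_refs(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            yield from _buffers_of(value, f"{prefix}{name}")


def _params_of(value, seen):
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for v in value.__dict__.values():
            yield from _params_of(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v, seen)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _params_of(v, seen)


def _named_params_of(value, name, seen):
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield name, value
    elif isinstance(value, Module):
        for sub, v in value.__dict__.items():
            yield from _named_params_of(v, f"{name}.{sub}", seen)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _named_params_of(v, f"{name}.{i}", seen)
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _named_params_of(v, f"{name}.{k}", seen)


def _modules_of(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _modules_of(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _modules_of(v)


def _buffers_of(value, prefix):
    if isinstance(value, BatchNorm1d):
        yield (f"{prefix}.running_mean", value, "running_mean")
        yield (f"{prefix}.running_var", value, "running_var")
    elif isinstance(value, Module):
        yield from value._buffer_refs(prefix + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _buffers_of(v, f"{prefix}.{i}")
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _buffers_of(v, f"{prefix}.{k}")


def kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    # uniform with variance 1/fan_in, so activation magnitudes are preserved
    # through deep affine stacks
    bound = np.sqrt(3.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    """Row-wise affine map ``x @ W + b`` with W of shape (in, out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = Parameter(kaiming_uniform(rng, d_in, (d_in, d_out)))
        self.b = Parameter(kaiming_uniform(rng, d_in, (d_out,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class BatchNorm1d(Module):
    """Feature-wise batch normalisation over the leading (row) axis.

    Training mode normalises by batch statistics and updates the running
    mean/variance; evaluation mode uses the running statistics, giving
    deterministic inference.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            n = x.shape[0]
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
            norm = centred * ((var + self.eps) ** -0.5)
        else:
            norm = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return norm * self.gamma + self.beta


class MLP(Module):
    """Two affine layers with a configurable hidden nonlinearity."""

    def __init__(self, d_in, d_hidden, d_out, rng, activation):
        super().__init__()
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.activation(self.fc1(x)))


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
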