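"""Parameterized layers built on the autograd engine."""

from __future__ import annotations

import copy

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "Conv2d"]

DTYPE = np.float32


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()

    def clone(self) -> "Module":
        return copy.deepcopy(self)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_std(fan_in: int, slope: float) -> float:
    # Kaiming initialization adjusted for the leaky-ReLU negative slope.
    return float(np.sqrt(2.0 / ((1.0 + slope**2) * fan_in)))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, slope: float = 0.2):
        std = _he_std(in_features, slope)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, slope: float = 0.2):
        fan_in = in_channels * kernel * kernel
        std = _he_std(fan_in, slope)
        self.weight = Tensor(
            rng.normal(0.0, std,
                       (out_channels, in_channels, kernel, kernel)).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True)
        self.pad = (kernel - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, pad=self.pad)
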