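"""Layer and optimizer primitives on top of the autograd core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, log_softmax, maxpool2d

__all__ = ["Module", "Conv2d", "Linear", "ReLU", "MaxPool2d", "Sequential",
           "GlobalAvgPool", "Adam", "cross_entropy"]


class Module:
    """Base class: parameter discovery via attributes, train/eval mode flag."""

    training: bool = True

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _iter_params(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            for m in _iter_modules(value):
                yield from m.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = list(self.parameters())
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _iter_params(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _iter_params(v)


def _iter_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _iter_modules(v)


class Conv2d(Module):
    """3x3 (or kxk) stride-1 convolution with He-normal init and 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.padding = kernel_size // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int = 2):
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride)


class GlobalAvgPool(Module):
    """NCHW -> NC global average pooling."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax(logits)."""
    logp = log_softmax(logits, axis=1)
    n = logits.shape[0]
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


class Adam:
    """Adam optimizer (Kingma & Ba) over the module's parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
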