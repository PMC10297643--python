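"""Layer modules and the SGD optimizer built on :mod:`cpcnn._tensor`.

Mirrors the familiar Module/Parameter idiom: submodules and parameters
registered by attribute assignment, recursive ``train()``/``eval()`` mode,
flat ``state_dict`` of NumPy arrays for checkpointing. Initialization is
He-normal for convolutions and linear layers, drawn from an explicit
per-module RNG so that model construction is reproducible from a seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "Identity",
    "SGD",
]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with attribute-based parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- registration -------------------------------------------------
    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        seen = set()
        for p in self._params.values():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
        for m in self._modules.values():
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- state ---------------------------------------------------------
    def state_dict(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            out[prefix + name] = np.array(b, copy=True)
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, p in self._params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()
        for name, b in self._buffers.items():
            np.copyto(b, np.asarray(state[name], dtype=b.dtype))
        for name, m in self._modules.items():
            sub = {
                k[len(name) + 1:]: v
                for k, v in state.items()
                if k.startswith(name + ".")
            }
            m.load_state_dict(sub)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (kernel_size, kernel_size, in_channels,
                                  out_channels)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.momentum, self.eps, training=self.training,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_features, in_features)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - np.float32(self.lr) * v
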