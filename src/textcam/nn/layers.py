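"""Layer/module abstractions over the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np

from textcam.nn import functional as F
from textcam.nn.autograd import Tensor


class Module:
    """Base class: tracks parameters, buffers and train/eval mode.

    Child modules, parameter tensors and buffer arrays are discovered from
    instance attributes (lists of modules are supported), giving torch-style
    dotted ``state_dict`` names.
    """

    def __init__(self) -> None:
        self.training = True

    # -- introspection ------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Copy matching entries in-place; returns the names that were skipped
        (missing from ``state``) when ``strict`` is False."""
        own: dict[str, np.ndarray] = {n: p.data for n, p in self.named_parameters()}
        own.update(dict(self.named_buffers()))
        skipped = []
        for name, arr in own.items():
            if name not in state:
                if strict:
                    raise KeyError(f"state dict missing entry {name!r}")
                skipped.append(name)
                continue
            src = state[name]
            if arr.shape != src.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model {arr.shape}, state {src.shape}"
                )
            arr[...] = src
        return skipped

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        # He-normal init (fan_out), matching common residual-net practice
        fan_out = out_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_out)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            momentum=self.momentum, eps=self.eps, training=self.training,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(rng.uniform(-bound, bound, out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
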