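"""A LeNet-style one-dimensional CNN baseline over the flattened token
sequence (channels = embedding dimension, length = H*W after padding)."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from textcam.nn import functional as F
from textcam.nn.autograd import Tensor
from textcam.nn.layers import Linear, Module


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_out = out_channels * kernel_size
        std = math.sqrt(2.0 / fan_out)
        # stored as a (F, C, 1, k) kernel so the 2D convolution kernel applies
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, 1, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, ln = x.shape
        x4 = _reshape(x, (n, c, 1, ln))
        out = F.conv2d(x4, self.weight, self.bias, stride=1, padding=0)
        return _reshape(out, (out.shape[0], out.shape[1], out.shape[3]))


def _reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    from textcam.nn.autograd import _make

    out = x.data.reshape(shape)

    def backward(g: np.ndarray) -> None:
        if x.needs_grad:
            x.accumulate(g.reshape(x.data.shape))

    return _make(out, (x,), backward)


class CNN1d(Module):
    """Two conv/pool blocks (kernel 5; 6 then 16 channels) and two dense
    layers, applied to a (D, L) embedded token sequence."""

    stage_names = ("conv1", "conv2")

    def __init__(self, in_channels: int, n_classes: int, seq_len: int = 625,
                 conv_channels: tuple[int, int] = (6, 16), hidden: int = 120,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.seq_len = seq_len
        c1, c2 = conv_channels
        self.conv1 = Conv1d(in_channels, c1, 5, rng=rng)
        self.conv2 = Conv1d(c1, c2, 5, rng=rng)
        l1 = (seq_len - 4) // 2
        l2 = (l1 - 4) // 2
        self.fc1 = Linear(c2 * l2, hidden, rng=rng)
        self.fc2 = Linear(hidden, n_classes, rng=rng)
        self._captured: dict[str, Tensor] = {}

    def forward(self, x: Tensor, capture: Sequence[str] = ()) -> Tensor:
        self._captured = {}
        out = F.relu(self.conv1(x))
        if "conv1" in capture:
            self._captured["conv1"] = out
        out = F.max_pool1d(out, 2, 2)
        out = F.relu(self.conv2(out))
        if "conv2" in capture:
            self._captured["conv2"] = out
        out = F.max_pool1d(out, 2, 2)
        out = F.flatten(out)
        out = F.relu(self.fc1(out))
        return self.fc2(out)

    def captured(self, name: str) -> Tensor:
        if name not in self._captured:
            raise KeyError(
                f"stage {name!r} was not captured; valid stages: {self.stage_names}"
            )
        return self._captured[name]
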