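"""An 18-layer residual network with a configurable input-channel count and
output head, suitable for small spatial inputs (e.g. 25x25 token grids).

The layout mirrors the standard torchvision resnet18 graph: 7x7 stem conv,
3x3/2 max pool, four stages of two basic blocks (64/128/256/512 channels),
global average pooling and a fully connected head. Stage outputs can be
captured during the forward pass so that class-activation mapping can read
activations and their gradients at any named stage.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from textcam.nn import functional as F
from textcam.nn.autograd import Tensor
from textcam.nn.layers import BatchNorm2d, Conv2d, Linear, Module


class BasicBlock(Module):
    def __init__(self, in_planes: int, planes: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.conv1 = Conv2d(in_planes, planes, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.downsample: Optional[list[Module]] = None
        if stride != 1 or in_planes != planes:
            self.downsample = [
                Conv2d(in_planes, planes, 1, stride=stride, rng=rng),
                BatchNorm2d(planes),
            ]

    def forward(self, x: Tensor) -> Tensor:
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x
        if self.downsample is not None:
            shortcut = self.downsample[1](self.downsample[0](x))
        return F.relu(F.add(out, shortcut))


class ResNet18(Module):
    """Residual classifier; ``stage_names`` are valid Grad-CAM targets."""

    stage_names = ("conv1", "layer1", "layer2", "layer3", "layer4")

    def __init__(self, in_channels: int = 3, n_classes: int = 1000,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.conv1 = Conv2d(in_channels, 64, 7, stride=2, padding=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.layer1 = self._make_stage(64, 64, stride=1, rng=rng)
        self.layer2 = self._make_stage(64, 128, stride=2, rng=rng)
        self.layer3 = self._make_stage(128, 256, stride=2, rng=rng)
        self.layer4 = self._make_stage(256, 512, stride=2, rng=rng)
        self.fc = Linear(512, n_classes, rng=rng)
        self._captured: dict[str, Tensor] = {}

    @staticmethod
    def _make_stage(in_planes: int, planes: int, stride: int,
                    rng: Optional[np.random.Generator]) -> list[BasicBlock]:
        return [BasicBlock(in_planes, planes, stride, rng=rng),
                BasicBlock(planes, planes, 1, rng=rng)]

    def forward(self, x: Tensor, capture: Sequence[str] = ()) -> Tensor:
        self._captured = {}
        out = F.relu(self.bn1(self.conv1(x)))
        if "conv1" in capture:
            self._captured["conv1"] = out
        out = F.max_pool2d(out, kernel=3, stride=2, padding=1)
        for name in ("layer1", "layer2", "layer3", "layer4"):
            for block in getattr(self, name):
                out = block(out)
            if name in capture:
                self._captured[name] = out
        out = F.global_avg_pool2d(out)
        return self.fc(out)

    def captured(self, name: str) -> Tensor:
        if name not in self._captured:
            raise KeyError(
                f"stage {name!r} was not captured; valid stages: {self.stage_names}"
            )
        return self._captured[name]


def adapt_for_transfer(model: ResNet18, donor_state: dict[str, np.ndarray]) -> list[str]:
    """Transfer-learning surgery: load every interior donor weight into
    ``model`` while leaving the (replaced) input convolution and output head
    at their fresh initialization.

    Entries whose names start with ``conv1.`` or ``fc.`` are skipped, as are
    donor entries with incompatible shapes elsewhere (there are none between
    two instances of this architecture). Returns the names actually loaded.
    """
    loaded = []
    own_params = {n: p.data for n, p in model.named_parameters()}
    own_params.update(dict(model.named_buffers()))
    for name, arr in donor_state.items():
        if name.startswith("conv1.") or name.startswith("fc."):
            continue
        if name in own_params and own_params[name].shape == arr.shape:
            own_params[name][...] = arr
            loaded.append(name)
    return loaded
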