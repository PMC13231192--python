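"""Per-instance convolutional feature extraction.

Two variants share one contract: images in, spatial feature maps out.

* ``resnet34`` — the standard 34-layer residual network with its final
  classification layer removed; C = 512 channels, total stride 32, so a
  256x256 input yields an 8x8 map.  ImageNet-pretrained weights can be
  loaded from a local ``.npz`` keyed by this module's state-dict names; they
  are optional and nothing here downloads anything.
* ``tinycnn`` — a fixed 4-block test backbone (conv3x3 stride 2, batch norm,
  ReLU per block; no conv biases); C = 64 channels, total stride 16, so a
  64x64 input yields a 4x4 map.  Small enough to train from scratch on a
  CPU in minutes.

Both operate on flattened (bag x instance) batches; callers reshape back to
bags.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["TinyCNN", "ResNet34", "build_backbone", "extract_features"]

_TINY_CHANNELS = (8, 16, 32, 64)


class TinyCNN(nn.Module):
    """4 x [conv3x3 (stride 2, no bias), BatchNorm, ReLU]; output C=64."""

    out_channels = 64
    total_stride = 16

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        layers = []
        in_ch = 3
        for ch in _TINY_CHANNELS:
            layers += [
                nn.Conv2d(in_ch, ch, 3, stride=2, padding=1, bias=False, rng=rng),
                nn.BatchNorm2d(ch),
                nn.ReLU(),
            ]
            in_ch = ch
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h < self.total_stride or w < self.total_stride:
            raise ValueError(
                f"input {h}x{w} too small for total stride {self.total_stride}"
            )
        return self.body(x)


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.downsample is None else self.downsample(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + identity).relu()


class ResNet34(nn.Module):
    """34-layer residual network, final FC removed; output C=512, stride 32."""

    out_channels = 512
    total_stride = 32
    _stage_plan = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        in_ch = 64
        stages = []
        for out_ch, blocks, stride in self._stage_plan:
            for b in range(blocks):
                stages.append(_BasicBlock(in_ch, out_ch, stride if b == 0 else 1, rng))
                in_ch = out_ch
        self.stages = nn.Sequential(*stages)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h < self.total_stride or w < self.total_stride:
            raise ValueError(
                f"input {h}x{w} too small for total stride {self.total_stride}"
            )
        out = self.bn1(self.conv1(x)).relu()
        out = F.max_pool2d(out, kernel=3, stride=2, padding=1)
        return self.stages(out)


def build_backbone(variant: str, rng: np.random.Generator | None = None,
                   pretrained_path: str | Path | None = None) -> nn.Module:
    """Construct a backbone by name; optionally load a local ``.npz`` weight file."""
    if variant == "tinycnn":
        model: nn.Module = TinyCNN(rng=rng)
    elif variant == "resnet34":
        model = ResNet34(rng=rng)
    else:
        raise ValueError(f"unknown backbone variant: {variant!r}")
    if pretrained_path is not None:
        with np.load(pretrained_path) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
    return model


def extract_features(backbone: nn.Module, images) -> Tensor:
    """Encode a flat instance batch [M,3,H,W] into feature maps [M,C,H',W']."""
    x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError(f"expected [M,3,H,W] images, got shape {x.shape}")
    return backbone(x)
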