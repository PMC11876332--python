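"""Residual regressor architectures.

``build_resnet18`` constructs the standard 18-layer residual network
(7x7/2 stem, 3x3/2 max pool, four stages of two basic blocks with 64/128/
256/512 channels, global average pooling) with the classification head
replaced by a single-output regression head.  It expects a 3-channel input.

``build_small_cnn`` is a 3-block CNN sized for desk-scale experiments on
native mel-spectrogram input (1 x n_mels x n_frames); it keeps frequency
position information by flattening rather than global pooling, which
matters because the temperature signature lives in *where* the event energy
sits on the mel axis.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Flatten,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = ["BasicBlock", "ResNetRegressor", "build_resnet18", "build_small_cnn"]


class BasicBlock(Module):
    """Two 3x3 conv-BN pairs with an identity (or 1x1 projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv: Conv2d | None = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn: BatchNorm2d | None = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return self.relu2(out + shortcut)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        # the sum node routes the gradient into both branches
        g_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(grad))))
        )
        if self.down_conv is None:
            g_short = grad
        else:
            g_short = self.down_conv.backward(self.down_bn.backward(grad))
        return g_main + g_short


class ResNetRegressor(Module):
    def __init__(self, body: Sequential, head: Linear):
        self.body = body
        self.head = head
        self.pretrained_loaded = False  # no pretrained weights ship offline

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head(self.body(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(grad))


def build_resnet18(rng: np.random.Generator | None = None, in_channels: int = 3) -> ResNetRegressor:
    """The 18-layer residual network with a 1-output regression head."""
    rng = rng or np.random.default_rng(0)
    layers: list[Module] = [
        Conv2d(in_channels, 64, 7, stride=2, pad=3, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, stride=2, pad=1),
    ]
    in_ch = 64
    for out_ch, stride in [(64, 1), (128, 2), (256, 2), (512, 2)]:
        layers.append(BasicBlock(in_ch, out_ch, stride, rng))
        layers.append(BasicBlock(out_ch, out_ch, 1, rng))
        in_ch = out_ch
    layers.append(GlobalAvgPool2d())
    return ResNetRegressor(Sequential(*layers), Linear(512, 1, rng=rng))


def build_small_cnn(
    rng: np.random.Generator | None = None,
    input_shape: tuple[int, int, int] = (1, 256, 10),
) -> ResNetRegressor:
    """3-block CNN + flatten head for desk-scale training runs."""
    rng = rng or np.random.default_rng(0)
    c, h, w = input_shape
    layers: list[Module] = []
    in_ch = c
    for out_ch in (8, 16, 32):
        layers += [
            Conv2d(in_ch, out_ch, 3, stride=1, pad=1, rng=rng),
            BatchNorm2d(out_ch),
            ReLU(),
            MaxPool2d(2),
        ]
        in_ch = out_ch
        h, w = h // 2, w // 2
        if h == 0 or w == 0:
            raise ValueError("input too small for the 3-block small CNN")
    # hidden dense layer lives in the body so the public head stays 1-output
    layers += [Flatten(), Linear(in_ch * h * w, 64, rng=rng), ReLU()]
    return ResNetRegressor(Sequential(*layers), Linear(64, 1, rng=rng))
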