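"""ResNet-18 backbone with a single-logit head.

Topology: 7x7/2 stem, 3x3/2 max pool, four stages of two basic blocks
(2 convs each, identity or 1x1-projection shortcut), global average pooling,
dropout, one output unit.  ``base_width`` scales all stage widths uniformly
(64 reproduces the published architecture; smaller values are for CI).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)


class BasicBlock(Layer):
    """Two 3x3 convolutions with a residual shortcut (projection on stride 2)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng, name: str):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng,
                            name=name + ".conv1")
        self.bn1 = BatchNorm2d(out_ch, name=name + ".bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng,
                            name=name + ".conv2")
        self.bn2 = BatchNorm2d(out_ch, name=name + ".bn2")
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng,
                                    name=name + ".downsample.0")
            self.down_bn = BatchNorm2d(out_ch, name=name + ".downsample.1")
        else:
            self.down_conv = self.down_bn = None
        self._relu_mask = None

    def parameters(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.down_conv is not None:
            mods += [self.down_conv, self.down_bn]
        return [p for m in mods for p in m.parameters()]

    def forward(self, x, train=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            identity = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            identity = x
        out = out + identity
        self._relu_mask = out > 0
        return out * self._relu_mask

    def backward(self, dout):
        dout = dout * self._relu_mask
        self._relu_mask = None
        d_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(dout)))))
        if self.down_conv is not None:
            d_skip = self.down_conv.backward(self.down_bn.backward(dout))
        else:
            d_skip = dout
        return d_main + d_skip

    def state_dict(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.down_conv is not None:
            mods += [self.down_conv, self.down_bn]
        d = {}
        for m in mods:
            d.update(m.state_dict())
        return d

    def load_state_dict(self, state):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.down_conv is not None:
            mods += [self.down_conv, self.down_bn]
        for m in mods:
            m.load_state_dict(state)


class ResNet18(Sequential):
    def __init__(self, in_channels: int, dropout: float = 0.3, base_width: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        w = base_width
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.in_channels = in_channels
        self.base_width = base_width
        stem = [
            Conv2d(in_channels, w, 7, stride=2, padding=3, rng=rng, name="conv1"),
            BatchNorm2d(w, name="bn1"),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        blocks: list[Layer] = []
        in_ch = w
        self.stages: list[list[BasicBlock]] = []
        for si, out_ch in enumerate(widths):
            stage = []
            for bi in range(2):
                stride = 2 if (si > 0 and bi == 0) else 1
                blk = BasicBlock(in_ch, out_ch, stride, rng, f"layer{si + 1}.{bi}")
                stage.append(blk)
                in_ch = out_ch
            blocks.extend(stage)
            self.stages.append(stage)
        self.dropout_layer = Dropout(dropout)
        self.fc = Linear(widths[-1], 1, rng=rng, name="fc")
        super().__init__(*stem, *blocks, AdaptiveAvgPool2d(), Flatten(),
                         self.dropout_layer, self.fc)

    def logits(self, x, train=False):
        return self.forward(np.ascontiguousarray(x, dtype=np.float32), train=train)

    def last_conv_block(self, stage: int = 4) -> BasicBlock:
        """Final block of the given stage (1-based), the Grad-CAM target."""
        return self.stages[stage - 1][-1]

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())


def resnet18_num_params(in_channels: int, base_width: int = 64) -> int:
    """Closed-form parameter count (convs without bias, BN affine, 1-unit head)."""
    w = base_width
    widths = [w, 2 * w, 4 * w, 8 * w]
    total = in_channels * w * 49 + 2 * w  # stem conv + bn
    in_ch = w
    for si, out_ch in enumerate(widths):
        for bi in range(2):
            total += in_ch * out_ch * 9 + 2 * out_ch      # conv1 + bn1
            total += out_ch * out_ch * 9 + 2 * out_ch     # conv2 + bn2
            if (si > 0 and bi == 0) or in_ch != out_ch:
                total += in_ch * out_ch + 2 * out_ch      # 1x1 projection + bn
            in_ch = out_ch
    total += widths[-1] * 1 + 1
    return total
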