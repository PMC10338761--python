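"""Residual networks (ResNet-18/50/101) and a small CNN for desk-scale runs.

The ResNet layouts follow the standard ImageNet designs: a 7x7/2 stem,
3x3/2 max pool, four stages of residual blocks — basic blocks stacked
[2,2,2,2] for ResNet-18, bottleneck blocks [3,4,6,3] for ResNet-50 and
[3,4,23,3] for ResNet-101 — then global average pooling and a fully
connected softmax head (2 classes here).  A residual block computes
F(x) + x; when the shapes differ the shortcut is a strided 1x1
convolution + batch norm.

With the 2-class head the trainable parameter counts are ~11.2 M
(ResNet-18), ~23.5 M (ResNet-50) and ~42.5 M (ResNet-101);
``count_parameters`` reports the actual count of any model.
"""
from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d,
                     Module, ReLU, Sequential)

VARIANTS = {
    "resnet18": ("basic", [2, 2, 2, 2]),
    "resnet50": ("bottleneck", [3, 4, 6, 3]),
    "resnet101": ("bottleneck", [3, 4, 23, 3]),
}


class BasicBlock(Module):
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    expansion = 1

    def __init__(self, cin: int, planes: int, stride: int, *, rng, dtype):
        cout = planes * self.expansion
        self.conv1 = Conv2d(cin, planes, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(planes, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(planes, cout, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu2 = ReLU()
        self.shortcut = None
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride, 0, rng=rng, dtype=dtype),
                BatchNorm2d(cout, dtype=dtype))

    def forward(self, x):
        identity = x if self.shortcut is None else self.shortcut(x)
        out = self.bn1(self.conv1(x))
        out = self.relu1(out)
        out = self.bn2(self.conv2(out))
        return self.relu2(out + identity)

    def backward(self, grad):
        grad = self.relu2.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        g_skip = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_main + g_skip


class Bottleneck(Module):
    """1x1 reduce, 3x3, 1x1 expand (x4) with shortcut."""

    expansion = 4

    def __init__(self, cin: int, planes: int, stride: int, *, rng, dtype):
        cout = planes * self.expansion
        self.conv1 = Conv2d(cin, planes, 1, 1, 0, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(planes, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(planes, planes, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(planes, dtype=dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(planes, cout, 1, 1, 0, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(cout, dtype=dtype)
        self.relu3 = ReLU()
        self.shortcut = None
        if stride != 1 or cin != cout:
            self.shortcut = Sequential(
                Conv2d(cin, cout, 1, stride, 0, rng=rng, dtype=dtype),
                BatchNorm2d(cout, dtype=dtype))

    def forward(self, x):
        identity = x if self.shortcut is None else self.shortcut(x)
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return self.relu3(out + identity)

    def backward(self, grad):
        grad = self.relu3.backward(grad)
        g = self.bn3.backward(grad)
        g = self.conv3.backward(g)
        g = self.relu2.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g_main = self.conv1.backward(g)
        g_skip = grad if self.shortcut is None else self.shortcut.backward(grad)
        return g_main + g_skip


class ResNet(Module):
    def __init__(self, block_type: str, counts: list[int], n_classes: int = 2,
                 in_channels: int = 3, *, rng: np.random.Generator,
                 dtype=np.float32):
        block_cls = BasicBlock if block_type == "basic" else Bottleneck
        self.stem = Sequential(
            Conv2d(in_channels, 64, 7, 2, 3, rng=rng, dtype=dtype),
            BatchNorm2d(64, dtype=dtype), ReLU(), MaxPool2d(3, 2, 1))
        blocks: list[Module] = []
        cin = 64
        for stage, (planes, n_blocks) in enumerate(
                zip((64, 128, 256, 512), counts)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(block_cls(cin, planes, stride, rng=rng,
                                        dtype=dtype))
                cin = planes * block_cls.expansion
        self.blocks = blocks
        self.pool = GlobalAvgPool()
        self.fc = Linear(cin, n_classes, rng=rng, dtype=dtype)

    def forward(self, x):
        x = self.stem(x)
        for blk in self.blocks:
            x = blk(x)
        return self.fc(self.pool(x))

    def backward(self, grad):
        grad = self.pool.backward(self.fc.backward(grad))
        for blk in reversed(self.blocks):
            grad = blk.backward(grad)
        return self.stem.backward(grad)


class TinyCNN(Module):
    """Two-stage small CNN for CPU-scale cross-validation experiments.

    Same structural idiom as the residual networks (conv-BN-ReLU stages,
    softmax head) but shallow enough to train in seconds on small FCR
    images.  The head flattens the feature map rather than averaging it:
    the class signal of an FCR lives at specific matrix positions, which
    global pooling would erase in so shallow a network.
    """

    def __init__(self, n_classes: int = 2, in_channels: int = 3, width: int = 8,
                 input_size: int = 32, *, rng: np.random.Generator,
                 dtype=np.float32):
        self.body = Sequential(
            Conv2d(in_channels, width, 3, 1, 1, rng=rng, dtype=dtype),
            BatchNorm2d(width, dtype=dtype), ReLU(), MaxPool2d(2, 2),
            Conv2d(width, 2 * width, 3, 1, 1, rng=rng, dtype=dtype),
            BatchNorm2d(2 * width, dtype=dtype), ReLU(), MaxPool2d(2, 2),
        )
        feat = 2 * width * (input_size // 4) ** 2
        self.fc = Linear(feat, n_classes, rng=rng, dtype=dtype)

    def forward(self, x):
        h = self.body(x)
        self._feat_shape = h.shape
        return self.fc(h.reshape(h.shape[0], -1))

    def backward(self, grad):
        g = self.fc.backward(grad)
        return self.body.backward(g.reshape(self._feat_shape))


def build_resnet(variant: str, n_classes: int = 2, in_channels: int = 3,
                 seed: int = 0, input_size: int = 224,
                 dtype=np.float32) -> Module:
    """Construct a residual network (or 'tiny' for the small CNN).

    ``input_size`` only matters for the tiny variant, whose flatten head
    depends on the image size; the residual networks are size-agnostic
    down to 32x32 thanks to global average pooling.
    """
    rng = np.random.default_rng(seed)
    if variant == "tiny":
        return TinyCNN(n_classes, in_channels, input_size=input_size,
                       rng=rng, dtype=dtype)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {sorted(VARIANTS)} or 'tiny'")
    block_type, counts = VARIANTS[variant]
    return ResNet(block_type, counts, n_classes, in_channels, rng=rng,
                  dtype=dtype)


def count_parameters(model: Module) -> int:
    """Total trainable parameter count."""
    return sum(p.size for p in model.parameters())
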