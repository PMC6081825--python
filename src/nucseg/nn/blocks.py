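"""Composite encoder-decoder building blocks.

``Block`` is the shared building unit of the symmetric family: a small
convolution stack (1x1, 3x3, or factorized 5 = 5x1 followed by 1x5) with
batch normalization, an additive identity path (1x1-projected when the
map counts differ), ReLU, and dropout.

The bottleneck units implement the asymmetric family: residual units
with a 1x1 reduction around a spatial convolution that is normal,
dilated, or factorized, plus dedicated downsampling and upsampling
variants that exchange max-pooling indices.
"""

from __future__ import annotations

import numpy as np

from .core import (F32, BatchNorm2d, Conv2d, ConvTranspose2x2, Dropout,
                   MaxPool2x2, MaxUnpool2x2, Param, ReLU)

KERNELS = ("1x1", "3x3", "factorized-5")


def _make_kernel_convs(rng, kernel: str, in_ch: int, out_ch: int) -> list[Conv2d]:
    if kernel == "1x1":
        return [Conv2d(rng, in_ch, out_ch, 1, 1)]
    if kernel == "3x3":
        return [Conv2d(rng, in_ch, out_ch, 3, 3)]
    if kernel == "factorized-5":
        return [Conv2d(rng, in_ch, out_ch, 5, 1),
                Conv2d(rng, out_ch, out_ch, 1, 5)]
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


class Block:
    """conv-stack -> BN, plus identity skip, -> ReLU -> dropout."""

    def __init__(self, rng, in_ch, out_ch, kernel="3x3", dropout_rate=0.1,
                 rng_ref=None):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.convs = _make_kernel_convs(rng, kernel, in_ch, out_ch)
        self.bn = BatchNorm2d(out_ch)
        self.proj = Conv2d(rng, in_ch, out_ch, 1, 1) if in_ch != out_ch else None
        self.relu = ReLU()
        self.drop = Dropout(dropout_rate, rng_ref if rng_ref is not None else [None])

    def params(self) -> list[Param]:
        out = []
        for c in self.convs:
            out += c.params()
        out += self.bn.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def layers(self):
        out = list(self.convs) + [self.bn]
        if self.proj is not None:
            out.append(self.proj)
        return out

    @property
    def conv_descriptors(self):
        return [c.descriptor for c in self.convs]

    def forward(self, x, train=False):
        h = x
        for c in self.convs:
            h = c.forward(h, train)
        h = self.bn.forward(h, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        y = self.relu.forward(h + s, train)
        return self.drop.forward(y, train)

    def backward(self, dy):
        dy = self.drop.backward(dy)
        dy = self.relu.backward(dy)
        dh = self.bn.backward(dy)
        for c in reversed(self.convs):
            dh = c.backward(dh)
        ds = dy if self.proj is None else self.proj.backward(dy)
        return dh + ds


class InitialBlock:
    """Stride-2 3x3 convolution concatenated with a 2x2 max-pool branch."""

    def __init__(self, rng, in_ch, out_ch=16):
        if out_ch <= in_ch:
            raise ValueError("initial block needs out_ch > in_ch")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv = Conv2d(rng, in_ch, out_ch - in_ch, 3, 3, stride=2)
        self.pool = MaxPool2x2()
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def layers(self):
        return [self.conv, self.bn]

    @property
    def conv_descriptors(self):
        return [self.conv.descriptor]

    def forward(self, x, train=False):
        a = self.conv.forward(x, train)
        b = self.pool.forward(x, train)
        y = np.concatenate([a, b], axis=1)
        return self.relu.forward(self.bn.forward(y, train), train)

    def backward(self, dy):
        dy = self.bn.backward(self.relu.backward(dy))
        split = self.out_ch - self.in_ch
        da = self.conv.backward(np.ascontiguousarray(dy[:, :split]))
        db = self.pool.backward(np.ascontiguousarray(dy[:, split:]))
        return da + db


class _BottleneckBase:
    def params(self):
        out = []
        for layer in self.layers():
            out += layer.params()
        return out


class RegularBottleneck(_BottleneckBase):
    """Residual unit: 1x1 reduce -> spatial conv -> 1x1 expand, identity skip.

    ``conv_type`` is "normal", "dilated:<d>", or "asymmetric".
    """

    def __init__(self, rng, ch, conv_type="normal", dropout_rate=0.1,
                 rng_ref=None, reduce_factor=4):
        self.ch = ch
        self.conv_type = conv_type
        r = max(ch // reduce_factor, 1)
        self.c1 = Conv2d(rng, ch, r, 1, 1)
        self.bn1, self.relu1 = BatchNorm2d(r), ReLU()
        if conv_type == "normal":
            self.mids = [Conv2d(rng, r, r, 3, 3)]
            self.dilation = 1
        elif conv_type.startswith("dilated:"):
            self.dilation = int(conv_type.split(":")[1])
            if self.dilation < 1:
                raise ValueError("dilation must be >= 1")
            self.mids = [Conv2d(rng, r, r, 3, 3, dilation=self.dilation)]
        elif conv_type == "asymmetric":
            self.mids = [Conv2d(rng, r, r, 5, 1), Conv2d(rng, r, r, 1, 5)]
            self.dilation = 1
        else:
            raise ValueError(f"unknown conv_type {conv_type!r}")
        self.bn2, self.relu2 = BatchNorm2d(r), ReLU()
        self.c3 = Conv2d(rng, r, ch, 1, 1)
        self.bn3 = BatchNorm2d(ch)
        self.drop = Dropout(dropout_rate, rng_ref if rng_ref is not None else [None])
        self.relu_out = ReLU()

    def layers(self):
        return [self.c1, self.bn1] + self.mids + [self.bn2, self.c3, self.bn3]

    @property
    def conv_descriptors(self):
        return [c.descriptor for c in [self.c1] + self.mids + [self.c3]]

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.c1.forward(x, train), train), train)
        for c in self.mids:
            h = c.forward(h, train)
        h = self.relu2.forward(self.bn2.forward(h, train), train)
        h = self.bn3.forward(self.c3.forward(h, train), train)
        h = self.drop.forward(h, train)
        return self.relu_out.forward(h + x, train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dh = self.drop.backward(dy)
        dh = self.c3.backward(self.bn3.backward(dh))
        dh = self.bn2.backward(self.relu2.backward(dh))
        for c in reversed(self.mids):
            dh = c.backward(dh)
        dh = self.c1.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dh + dy


class DownBottleneck(_BottleneckBase):
    """Downsampling residual unit; skip is a max-pool with channel zero-pad.

    The pooling indices are retained for the paired upsampling unit.
    """

    def __init__(self, rng, in_ch, out_ch, dropout_rate=0.1, rng_ref=None):
        self.in_ch, self.out_ch = in_ch, out_ch
        r = max(out_ch // 4, 1)
        self.c1 = Conv2d(rng, in_ch, r, 2, 2, stride=2)
        self.bn1, self.relu1 = BatchNorm2d(r), ReLU()
        self.c2 = Conv2d(rng, r, r, 3, 3)
        self.bn2, self.relu2 = BatchNorm2d(r), ReLU()
        self.c3 = Conv2d(rng, r, out_ch, 1, 1)
        self.bn3 = BatchNorm2d(out_ch)
        self.drop = Dropout(dropout_rate, rng_ref if rng_ref is not None else [None])
        self.pool = MaxPool2x2()
        self.relu_out = ReLU()

    def layers(self):
        return [self.c1, self.bn1, self.c2, self.bn2, self.c3, self.bn3]

    @property
    def conv_descriptors(self):
        return [self.c1.descriptor, self.c2.descriptor, self.c3.descriptor]

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.c1.forward(x, train), train), train)
        h = self.relu2.forward(self.bn2.forward(self.c2.forward(h, train), train), train)
        h = self.bn3.forward(self.c3.forward(h, train), train)
        h = self.drop.forward(h, train)
        s = self.pool.forward(x, train)
        pad = self.out_ch - self.in_ch
        if pad:
            s = np.pad(s, ((0, 0), (0, pad), (0, 0), (0, 0)))
        return self.relu_out.forward(h + s, train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dh = self.drop.backward(dy)
        dh = self.c3.backward(self.bn3.backward(dh))
        dh = self.c2.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.c1.backward(self.bn1.backward(self.relu1.backward(dh)))
        ds = self.pool.backward(np.ascontiguousarray(dy[:, :self.in_ch]))
        return dh + ds


class UpBottleneck(_BottleneckBase):
    """Upsampling residual unit; skip is 1x1 conv + max-unpool with the
    indices stored by its paired :class:`DownBottleneck`."""

    def __init__(self, rng, in_ch, out_ch, paired_down: DownBottleneck,
                 dropout_rate=0.1, rng_ref=None):
        if paired_down.in_ch != out_ch:
            raise ValueError("unpool channel count must match paired pooling")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.paired = paired_down
        r = max(out_ch // 4, 1)
        self.c1 = Conv2d(rng, in_ch, r, 1, 1)
        self.bn1, self.relu1 = BatchNorm2d(r), ReLU()
        self.up = ConvTranspose2x2(rng, r, r)
        self.bn2, self.relu2 = BatchNorm2d(r), ReLU()
        self.c3 = Conv2d(rng, r, out_ch, 1, 1)
        self.bn3 = BatchNorm2d(out_ch)
        self.skip_conv = Conv2d(rng, in_ch, out_ch, 1, 1)
        self.skip_bn = BatchNorm2d(out_ch)
        self.unpool = MaxUnpool2x2()
        self.drop = Dropout(dropout_rate, rng_ref if rng_ref is not None else [None])
        self.relu_out = ReLU()

    def layers(self):
        return [self.c1, self.bn1, self.up, self.bn2, self.c3, self.bn3,
                self.skip_conv, self.skip_bn]

    @property
    def conv_descriptors(self):
        return [self.c1.descriptor, self.up.descriptor, self.c3.descriptor]

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.c1.forward(x, train), train), train)
        h = self.relu2.forward(self.bn2.forward(self.up.forward(h, train), train), train)
        h = self.bn3.forward(self.c3.forward(h, train), train)
        h = self.drop.forward(h, train)
        s = self.skip_bn.forward(self.skip_conv.forward(x, train), train)
        s = self.unpool.forward_with_indices(s, self.paired.pool.indices)
        return self.relu_out.forward(h + s, train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dh = self.drop.backward(dy)
        dh = self.c3.backward(self.bn3.backward(dh))
        dh = self.up.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.c1.backward(self.bn1.backward(self.relu1.backward(dh)))
        ds = self.skip_conv.backward(self.skip_bn.backward(self.unpool.backward(dy)))
        return dh + ds
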