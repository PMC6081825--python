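"""Declarative construction of the encoder-decoder model families.

Two families are provided:

* ``symmetric`` — ``n_modules`` encoder blocks (each followed by 2x2
  max-pooling) mirrored by ``n_modules`` decoder blocks (each preceded
  by max-unpooling driven by the matching encoder's pooling indices).
  Feature maps follow a three-tier plan, default ``(32, 64, 128)``:
  the first third of the blocks at the initial width, the middle third
  (plus any remainder) at the middle width, the last third at the final
  width, mirrored on the way up.
* ``enet`` — an asymmetric network of bottleneck units: an initial
  downsampling block, two downsampling stages whose units mix normal,
  dilated and factorized (asymmetric) convolutions, and a deliberately
  shallower decoder with two upsampling stages.

Both end in a 1x1 (or transposed) projection to ``out_classes`` followed
by a per-pixel softmax, so a forward pass returns probability maps that
sum to one at every pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn.blocks import (Block, DownBottleneck, InitialBlock,
                        RegularBottleneck, UpBottleneck)
from .nn.core import (F32, BatchNorm2d, Conv2d, ConvTranspose2x2,
                      MaxPool2x2, MaxUnpool2x2, Param, params_checksum,
                      softmax_channels)

FAMILIES = ("symmetric", "enet")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of an encoder-decoder architecture."""

    family: str = "symmetric"
    n_modules: int = 3
    in_channels: int = 1
    out_classes: int = 2
    feature_plan: tuple[int, int, int] = (32, 64, 128)
    dropout_rate: float = 0.1
    up_mode: str = "unpool"  # or "transposed"
    kernel: str = "3x3"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "symmetric" and not 3 <= self.n_modules <= 10:
            raise ValueError("n_modules must be in 3..10 for the symmetric family")
        if self.in_channels < 1 or self.out_classes < 2:
            raise ValueError("need >=1 input channel and >=2 output classes")
        if self.up_mode not in ("unpool", "transposed"):
            raise ValueError("up_mode must be 'unpool' or 'transposed'")

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.n_modules if self.family == "symmetric" else 8

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_plan"] = list(self.feature_plan)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["feature_plan"] = tuple(d.get("feature_plan", (32, 64, 128)))
        return cls(**d)


def plan_channels(n_modules: int, plan: tuple[int, int, int]) -> list[int]:
    """Per-block encoder widths: thirds with the remainder given to the
    middle tier."""
    lo = n_modules // 3
    mid = n_modules - 2 * lo
    return [plan[0]] * lo + [plan[1]] * mid + [plan[2]] * lo


class _NetBase:
    def params(self) -> list[Param]:
        out = []
        for b in self._param_blocks():
            out += b.params()
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def checksum(self) -> str:
        return params_checksum(self.params())

    def reseed_dropout(self, seed: int) -> None:
        self.rng_ref[0] = np.random.default_rng(seed)

    def _bn_layers(self):
        for b in self._param_blocks():
            for layer in (b.layers() if hasattr(b, "layers") else [b]):
                if isinstance(layer, BatchNorm2d):
                    yield layer

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params():
            a = next(it)
            if a.shape != p.data.shape:
                raise ValueError("checkpoint/spec shape mismatch")
            p.data[...] = a
        for bn in self._bn_layers():
            bn.running_mean[...] = next(it)
            bn.running_var[...] = next(it)


class SymmetricNet(_NetBase):
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.family != "symmetric":
            raise ValueError("spec.family must be 'symmetric'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng_ref = [np.random.default_rng(seed + 1)]
        widths = plan_channels(spec.n_modules, spec.feature_plan)
        self.enc_widths = widths
        self.enc_blocks, self.pools = [], []
        prev = spec.in_channels
        for w in widths:
            self.enc_blocks.append(Block(rng, prev, w, spec.kernel,
                                         spec.dropout_rate, self.rng_ref))
            self.pools.append(MaxPool2x2())
            prev = w
        self.dec_blocks, self.ups = [], []
        dec_out = widths[-2::-1] + [spec.feature_plan[0]]
        for i, w in enumerate(dec_out):
            cur = widths[-1 - i]
            if spec.up_mode == "unpool":
                self.ups.append(MaxUnpool2x2())
            else:
                self.ups.append(ConvTranspose2x2(rng, cur, cur))
            self.dec_blocks.append(Block(rng, cur, w, spec.kernel,
                                         spec.dropout_rate, self.rng_ref))
        self.classifier = Conv2d(rng, dec_out[-1], spec.out_classes, 1, 1)

    def _param_blocks(self):
        blocks = list(self.enc_blocks) + list(self.dec_blocks) + [self.classifier]
        if self.spec.up_mode == "transposed":
            blocks += list(self.ups)
        return blocks

    @property
    def trunk_parameter_count(self) -> int:
        return self.parameter_count - sum(p.size for p in self.classifier.params())

    def forward_trunk(self, x, train=False):
        factor = self.spec.downsample_factor
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(
                f"input sides must be divisible by {factor}; got {x.shape[2:]}")
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = pool.forward(blk.forward(h, train), train)
        for i, (up, blk) in enumerate(zip(self.ups, self.dec_blocks)):
            if self.spec.up_mode == "unpool":
                h = up.forward_with_indices(h, self.pools[-1 - i].indices)
            else:
                h = up.forward(h, train)
            h = blk.forward(h, train)
        return h

    def backward_trunk(self, dh):
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dh = self.dec_blocks[i].backward(dh)
            dh = self.ups[i].backward(dh)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = self.enc_blocks[i].backward(dh)
        return dh

    def forward(self, x, train=False):
        h = self.forward_trunk(x, train)
        logits = self.classifier.forward(h, train)
        return softmax_channels(logits)

    def backward(self, dlogits):
        return self.backward_trunk(self.classifier.backward(dlogits))


class MultitaskNet(SymmetricNet):
    """Shared symmetric trunk with two 1x1 softmax heads (region, boundary)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__(spec, seed)
        rng = np.random.default_rng(seed + 1000)
        width = self.classifier.in_ch
        self.head_region = self.classifier
        self.head_boundary = Conv2d(rng, width, spec.out_classes, 1, 1)

    def _param_blocks(self):
        return super()._param_blocks() + [self.head_boundary]

    @property
    def trunk_parameter_count(self) -> int:
        heads = sum(p.size for p in self.head_region.params())
        heads += sum(p.size for p in self.head_boundary.params())
        return self.parameter_count - heads

    def forward(self, x, train=False):
        h = self.forward_trunk(x, train)
        pr = softmax_channels(self.head_region.forward(h, train))
        pb = softmax_channels(self.head_boundary.forward(h, train))
        return pr, pb

    def backward(self, dlogits_region, dlogits_boundary):
        dh = self.head_region.backward(dlogits_region)
        dh = dh + self.head_boundary.backward(dlogits_boundary)
        return self.backward_trunk(dh)


# Declared unit list of the asymmetric family (stage -> unit kinds).
ENET_STAGE2_TYPES = ("normal", "dilated:2", "asymmetric", "dilated:4",
                     "normal", "dilated:8", "asymmetric", "dilated:16")


class EnetNet(_NetBase):
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.family != "enet":
            raise ValueError("spec.family must be 'enet'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng_ref = [np.random.default_rng(seed + 1)]
        rr = self.rng_ref
        self.initial = InitialBlock(rng, spec.in_channels, 16)
        self.down1 = DownBottleneck(rng, 16, 64, 0.01, rr)
        self.stage1 = [RegularBottleneck(rng, 64, "normal", 0.01, rr)
                       for _ in range(4)]
        self.down2 = DownBottleneck(rng, 64, 128, spec.dropout_rate, rr)
        self.stage2 = [RegularBottleneck(rng, 128, t, spec.dropout_rate, rr)
                       for t in ENET_STAGE2_TYPES]
        self.up1 = UpBottleneck(rng, 128, 64, self.down2, spec.dropout_rate, rr)
        self.dec1 = RegularBottleneck(rng, 64, "normal", spec.dropout_rate, rr)
        self.up2 = UpBottleneck(rng, 64, 16, self.down1, spec.dropout_rate, rr)
        self.dec2 = RegularBottleneck(rng, 16, "normal", spec.dropout_rate, rr)
        self.fullconv = ConvTranspose2x2(rng, 16, spec.out_classes)

        self.encoder_units = ([self.initial, self.down1] + self.stage1
                              + [self.down2] + self.stage2)
        self.decoder_units = [self.up1, self.dec1, self.up2, self.dec2,
                              self.fullconv]

    def _param_blocks(self):
        return self.encoder_units + self.decoder_units

    def forward(self, x, train=False):
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError(f"input sides must be divisible by 8; got {x.shape[2:]}")
        h = x
        for u in self.encoder_units:
            h = u.forward(h, train)
        for u in self.decoder_units[:-1]:
            h = u.forward(h, train)
        logits = self.fullconv.forward(h, train)
        return softmax_channels(logits)

    def backward(self, dlogits):
        dh = self.fullconv.backward(dlogits)
        for u in reversed(self.decoder_units[:-1]):
            dh = u.backward(dh)
        for u in reversed(self.encoder_units):
            dh = u.backward(dh)
        return dh


class SegmentationModel:
    """A built network together with its spec; the unit every other module
    passes around."""

    def __init__(self, spec: NetworkSpec, net: _NetBase):
        self.spec = spec
        self.net = net

    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count

    @property
    def downsample_factor(self) -> int:
        return self.spec.downsample_factor

    def forward(self, x: np.ndarray, train: bool = False):
        return self.net.forward(np.asarray(x, dtype=F32), train)

    def backward(self, dlogits):
        return self.net.backward(dlogits)

    def params(self):
        return self.net.params()

    def checksum(self) -> str:
        return self.net.checksum()

    def save(self, path) -> None:
        arrays = {f"arr{i}": a for i, a in enumerate(self.net.state_arrays())}
        meta = json.dumps({"spec": self.spec.to_dict(),
                           "multitask": isinstance(self.net, MultitaskNet)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = [z[f"arr{i}"] for i in range(len(z.files) - 1)]
        spec = NetworkSpec.from_dict(meta["spec"])
        if meta.get("multitask"):
            model = build_multitask(spec, seed=0)
        elif spec.family == "symmetric":
            model = build_symmetric(spec=spec, seed=0)
        else:
            model = build_enet(spec=spec, seed=0)
        model.net.load_state(arrays)
        return model


def build_symmetric(n_modules: int = 3, in_channels: int = 1,
                    out_classes: int = 2, spec: NetworkSpec | None = None,
                    seed: int = 0, **kw) -> SegmentationModel:
    if spec is None:
        spec = NetworkSpec(family="symmetric", n_modules=n_modules,
                           in_channels=in_channels, out_classes=out_classes, **kw)
    return SegmentationModel(spec, SymmetricNet(spec, seed))


def build_enet(in_channels: int = 1, out_classes: int = 2,
               spec: NetworkSpec | None = None, seed: int = 0,
               **kw) -> SegmentationModel:
    if spec is None:
        spec = NetworkSpec(family="enet", in_channels=in_channels,
                           out_classes=out_classes, **kw)
    return SegmentationModel(spec, EnetNet(spec, seed))


def build_multitask(spec: NetworkSpec, seed: int = 0) -> SegmentationModel:
    if spec.family != "symmetric":
        raise ValueError("multitask trunk uses the symmetric family")
    return SegmentationModel(spec, MultitaskNet(spec, seed))


def receptive_field(descriptors: list[dict]) -> int:
    """Analytic receptive-field recursion over an ordered conv chain."""
    rf, jump = 1, 1
    for d in descriptors:
        k = max(d["kh"], d["kw"])
        rf += (k - 1) * d["dilation"] * jump
        jump *= d["stride"]
    return rf
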