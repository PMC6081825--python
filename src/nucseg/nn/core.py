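"""Minimal CPU neural-network layers with explicit backward passes.

Everything operates on float32 NCHW arrays.  Layers cache what their
backward pass needs during ``forward`` and release it on ``backward``.
The output softmax is evaluated in ``forward`` but, for efficiency,
training drives ``backward`` with the gradient w.r.t. the *logits*
(softmax + cross-entropy folded together in the loss).
"""

from __future__ import annotations

import hashlib

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with an accumulated gradient.

    ``decay`` marks parameters subject to L2 weight decay (convolution
    weights only; biases and normalization affines are exempt).
    """

    __slots__ = ("data", "grad", "decay", "name")

    def __init__(self, data: np.ndarray, decay: bool = False, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.decay = decay
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(F32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution with 'same' padding (stride 1) or exact halving.

    Supports rectangular kernels (for factorized 5x1/1x5), dilation and
    stride.  For stride ``s`` the output is H//s x W//s, with zero padding
    chosen so that stride-1 convolutions preserve spatial dims.
    """

    def __init__(self, rng, in_ch, out_ch, kh, kw, stride=1, dilation=1, bias=True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.dilation = dilation
        eff_kh = dilation * (kh - 1) + 1
        eff_kw = dilation * (kw - 1) + 1
        if stride == 1:
            self.ph, self.pw = (eff_kh - 1) // 2, (eff_kw - 1) // 2
        else:
            # exact halving: zero pad only when the kernel overhangs
            self.ph = max((eff_kh - stride + 1) // 2, 0)
            self.pw = max((eff_kw - stride + 1) // 2, 0)
        self.weight = Param(
            _he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw),
            decay=True, name="conv.weight",
        )
        self.bias = Param(np.zeros(out_ch), name="conv.bias") if bias else None
        self._cache = None

    # descriptor used by the receptive-field oracle
    @property
    def descriptor(self):
        return {"kh": self.kh, "kw": self.kw, "stride": self.stride,
                "dilation": self.dilation}

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, xp, oh, ow):
        """Patch matrix in (C*kh*kw, n*oh*ow) layout, ready for one GEMM."""
        n, c = xp.shape[:2]
        s, d = self.stride, self.dilation
        cols = np.empty((c, self.kh, self.kw, n, oh, ow), dtype=F32)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, i, j] = xp[:, :, i * d: i * d + oh * s: s,
                                   j * d: j * d + ow * s: s].transpose(1, 0, 2, 3)
        return cols.reshape(c * self.kh * self.kw, n * oh * ow)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        s = self.stride
        oh, ow = h // s, w // s
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw))) \
            if (self.ph or self.pw) else x
        cols2d = self._im2col(xp, oh, ow)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y2d = wmat @ cols2d  # (out, n*P): one large GEMM
        y = np.ascontiguousarray(
            y2d.reshape(self.out_ch, n, oh * ow).transpose(1, 0, 2))
        if self.bias is not None:
            y += self.bias.data[:, None]
        self._cache = (cols2d, xp.shape, (oh, ow))
        return y.reshape(n, self.out_ch, oh, ow)

    def backward(self, dy):
        cols2d, xp_shape, (oh, ow) = self._cache
        self._cache = None
        n = dy.shape[0]
        dy2d = np.ascontiguousarray(dy.reshape(n, self.out_ch, oh * ow)
                                    .transpose(1, 0, 2)).reshape(
                                        self.out_ch, n * oh * ow)
        self.weight.grad += (dy2d @ cols2d.T).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy2d.sum(axis=1)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        dcols = (wmat.T @ dy2d).reshape(
            self.in_ch, self.kh, self.kw, n, oh, ow)
        dxp = np.zeros(xp_shape, dtype=F32)
        s, d = self.stride, self.dilation
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i * d: i * d + oh * s: s,
                    j * d: j * d + ow * s: s] += \
                    dcols[:, i, j].transpose(1, 0, 2, 3)
        if self.ph or self.pw:
            dxp = dxp[:, :, self.ph: dxp.shape[2] - self.ph,
                      self.pw: dxp.shape[3] - self.pw]
        return dxp


class ConvTranspose2x2(Layer):
    """Transposed convolution, kernel 2, stride 2: exact spatial doubling."""

    def __init__(self, rng, in_ch, out_ch, bias=True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch),
                            decay=True, name="convT.weight")
        self.bias = Param(np.zeros(out_ch), name="convT.bias") if bias else None
        self._cache = None

    @property
    def descriptor(self):
        return {"kh": 2, "kw": 2, "stride": 1, "dilation": 1}

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        # y[n,o,2i+a,2j+b] = sum_c W[c,o,a,b] x[n,c,i,j]  (non-overlapping)
        y = np.einsum("nchw,coab->nohawb", x, self.weight.data, optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = x
        return np.ascontiguousarray(y)

    def backward(self, dy):
        x = self._cache
        self._cache = None
        n, _, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, self.out_ch, h, 2, w, 2)
        self.weight.grad += np.einsum("nohawb,nchw->coab", dyb, x, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(
            np.einsum("nohawb,coab->nchw", dyb, self.weight.data, optimize=True))


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.ch = ch
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(ch), name="bn.gamma")
        self.beta = Param(np.zeros(ch), name="bn.beta")
        self.running_mean = np.zeros(ch, dtype=F32)
        self.running_var = np.ones(ch, dtype=F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]
        self._cache = (xhat, inv, train)
        return y.astype(F32, copy=False)

    def backward(self, dy):
        xhat, inv, train = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return (dy * g).astype(F32, copy=False)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = g * (dy - dy_sum / m - xhat * dyx_sum / m)
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, F32(0.0))  # np.maximum propagates NaN

    def backward(self, dy):
        mask = self._mask
        self._mask = None
        return np.where(mask, dy, F32(0.0))


class Dropout(Layer):
    """Inverted dropout driven by an externally owned RNG (for seeding)."""

    def __init__(self, rate: float, rng_ref):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng_ref = rng_ref  # mutable single-element list holding a Generator
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng_ref[0].random(x.shape) < keep).astype(F32) / F32(keep)
        self._mask = mask
        return x * mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        mask = self._mask
        self._mask = None
        return dy * mask


class MaxPool2x2(Layer):
    """2x2 max pooling; stores flat argmax indices for paired unpooling."""

    def __init__(self):
        self.indices = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xb = np.ascontiguousarray(xb).reshape(n, c, h // 2, w // 2, 4)
        idx = xb.argmax(axis=-1)
        y = np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]
        self.indices = idx
        self._in_shape = x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(out, self.indices[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out).reshape(n, c, h, w)


class MaxUnpool2x2(Layer):
    """Places each value at the argmax position recorded by a MaxPool2x2."""

    def __init__(self):
        self._idx = None

    def forward_with_indices(self, x, indices):
        n, c, h, w = x.shape
        out = np.zeros((n, c, h, w, 4), dtype=F32)
        np.put_along_axis(out, indices[..., None], x[..., None], axis=-1)
        out = out.reshape(n, c, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = indices
        return np.ascontiguousarray(out).reshape(n, c, 2 * h, 2 * w)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, c, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        dyb = np.ascontiguousarray(dyb).reshape(n, c, h, w, 4)
        idx = self._idx
        self._idx = None
        return np.take_along_axis(dyb, idx[..., None], axis=-1)[..., 0]


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z, dtype=F32)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_logits_grad(probs, target, class_weights=None):
    """Mean weighted cross entropy and its gradient w.r.t. the logits.

    ``target`` is an integer (N, H, W) class map; ``probs`` the softmax
    output (N, C, H, W).  Returns ``(loss, dlogits)``.
    """
    n, c, h, w = probs.shape
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, target[:, None], F32(1.0), axis=1)
    if class_weights is not None:
        wmap = np.asarray(class_weights, dtype=F32)[target][:, None]
    else:
        wmap = F32(1.0)
    logp = np.log(np.clip(probs, 1e-12, None))
    denom = F32(n * h * w)
    loss = float(-(onehot * logp * wmap).sum() / denom)
    dlogits = (probs - onehot) * wmap / denom
    return loss, dlogits.astype(F32, copy=False)


def params_checksum(params: list[Param]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
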