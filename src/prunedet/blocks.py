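"""Network building blocks.

Three bespoke blocks drive the detector's accuracy story:

* :class:`CSPP` — a stem block that fuses a learned stride-2 convolution with
  a fixed Prewitt edge-magnitude branch and a stride-1 max-pooling branch.
  The fixed difference kernels inject an explicit edge prior at the very
  first stage, where blurred lesion boundaries are otherwise easy to lose.
* :class:`DynamicConv2d` — convolution whose kernel is an input-conditioned
  convex combination of a bank of ``K`` kernels; the mixture weights come
  from a squeeze (global average pool) followed by a two-layer MLP and a
  temperature softmax.  Used inside :class:`C3k2` bottlenecks to form the
  dynamic variant ("DCC").
* :class:`CPCA` — channel-prior convolutional attention: sequential channel
  attention (shared MLP over average- and max-pooled channel vectors) and
  spatial attention (5x5 depthwise convolution plus multi-scale depthwise
  strip branches and a 1x1 channel mixer), applied before the detection
  head.

The remaining classes mirror the host YOLO-family layer vocabulary
(Conv-BN-SiLU, Bottleneck, C3k, C3k2, SPPF, C2PSA, anchor-free Detect head
with distribution-focal box regression) so that parameter/FLOP accounting of
the assembled graphs is comparable with the published nano-scale models.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .nn import (Tensor, cat, conv2d, max_pool2d, Module, ModuleList,
                 Sequential, Identity, Conv2d, BatchNorm2d, MaxPool2d)

__all__ = [
    "ConvBNAct", "DWConv", "prewitt_filter", "CSPP", "DynamicConv2d",
    "Bottleneck", "C3k", "C3k2", "SPPF", "Attention", "PSABlock", "C2PSA",
    "CPCA", "DFL", "Detect", "PREWITT_GX", "PREWITT_GY",
]

# Horizontal-difference kernel (zero middle column); the vertical kernel is
# its transpose.
PREWITT_GX = np.array([[-1.0, 0.0, 1.0]] * 3, dtype=np.float32)
PREWITT_GY = PREWITT_GX.T.copy()


class ConvBNAct(Module):
    """Convolution + batch norm + SiLU (the host family's ``Conv``)."""

    def __init__(self, c1: int, c2: int, k=1, s: int = 1, g: int = 1,
                 act: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, groups=g, bias=False, rng=rng)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


def DWConv(c1: int, c2: int, k=3, s: int = 1, act: bool = True, rng=None) -> ConvBNAct:
    return ConvBNAct(c1, c2, k, s, g=math.gcd(c1, c2), act=act, rng=rng)


# ---------------------------------------------------------------------------
# CSPP
# ---------------------------------------------------------------------------

def _replicate_pad1(x: Tensor) -> Tensor:
    """Edge-replicate padding of 1 pixel on both spatial axes."""
    x = cat([x[:, :, 0:1, :], x, x[:, :, -1:, :]], axis=2)
    return cat([x[:, :, :, 0:1], x, x[:, :, :, -1:]], axis=3)


def prewitt_filter(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Depthwise Prewitt edge magnitude.

    Each channel is correlated with the horizontal and the vertical
    difference kernel and the two responses are combined as a Euclidean
    magnitude.  The border is edge-replicated so a constant input has an
    exactly zero response everywhere (zero padding would fabricate an edge
    at the frame).  ``eps`` inside the square root keeps the gradient finite
    at zero response; subtracting ``sqrt(eps)`` keeps constants at zero.
    """
    c = x.data.shape[1]
    if x.data.shape[2] < 3 or x.data.shape[3] < 3:
        raise ValueError("prewitt_filter needs spatial dims >= 3")
    wx = Tensor(np.broadcast_to(PREWITT_GX, (c, 1, 3, 3)).copy())
    wy = Tensor(np.broadcast_to(PREWITT_GY, (c, 1, 3, 3)).copy())
    xp = _replicate_pad1(x)
    gx = conv2d(xp, wx, None, stride=1, padding=0, groups=c)
    gy = conv2d(xp, wy, None, stride=1, padding=0, groups=c)
    return (gx * gx + gy * gy + eps).sqrt() - math.sqrt(eps)


class CSPP(Module):
    """Stem block: conv -> {Prewitt edge magnitude || 3x3 max pool} -> fuse.

    The first 3x3 convolution has stride 2 (spatial compression and channel
    expansion); both branches preserve its spatial size, are concatenated to
    twice the branch width, and are fused by a 3x3 and then a 1x1
    convolution.
    """

    def __init__(self, c1: int, c2: int, c_mid: int, c_hid: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.cv1 = ConvBNAct(c1, c_mid, 3, 2, rng=rng)
        self.pool = MaxPool2d(3, 1, 1)
        self.cv2 = ConvBNAct(2 * c_mid, c_hid, 3, 1, rng=rng)
        self.cv3 = ConvBNAct(c_hid, c2, 1, 1, rng=rng)
        self.c_mid = c_mid

    def forward(self, x):
        x1 = self.cv1(x)
        edge = prewitt_filter(x1)
        pooled = self.pool(x1)
        x2 = cat([edge, pooled], axis=1)
        if x2.data.shape[1] != 2 * self.c_mid:
            raise ValueError("CSPP concat width mismatch")
        return self.cv3(self.cv2(x2))


# ---------------------------------------------------------------------------
# Dynamic convolution
# ---------------------------------------------------------------------------

class DynamicConv2d(Module):
    """Input-conditioned mixture-of-kernels convolution.

    A bank of ``K`` kernels is combined per sample with attention weights
    ``theta = softmax(FC2(relu(FC1(gap(x)))) / temperature)``; the aggregated
    kernel is then applied as one ordinary convolution, so inference cost
    matches a static convolution of the same shape.
    """

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1, K: int = 3,
                 reduction: int = 4, temperature: float = 1.0,
                 attention_norm: str = "softmax",
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if K < 1:
            raise ValueError("kernel bank needs K >= 1")
        if attention_norm not in ("softmax", "sigmoid"):
            raise ValueError("attention_norm must be 'softmax' or 'sigmoid'")
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s, self.K = c1, c2, k, s, K
        self.temperature = temperature
        self.attention_norm = attention_norm
        fan_in = c1 * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (K, c2, c1, k, k)),
                             requires_grad=True)
        hidden = max(c1 // reduction, 4)
        b1 = 1.0 / math.sqrt(c1)
        self.fc1_w = Tensor(rng.uniform(-b1, b1, (hidden, c1)), requires_grad=True)
        self.fc1_b = Tensor(np.zeros(hidden), requires_grad=True)
        b2 = 1.0 / math.sqrt(hidden)
        self.fc2_w = Tensor(rng.uniform(-b2, b2, (K, hidden)), requires_grad=True)
        self.fc2_b = Tensor(np.zeros(K), requires_grad=True)

    def attention(self, x: Tensor) -> Tensor:
        """Per-sample mixture weights theta, shape (N, K).

        With the default softmax normalization the rows sum to 1 (convex
        mixture); the sigmoid alternative gates each kernel independently.
        """
        g = x.mean(axis=(2, 3))                      # (N, C) global average pool
        h = (g @ self.fc1_w.transpose(1, 0) + self.fc1_b).relu()
        logits = (h @ self.fc2_w.transpose(1, 0) + self.fc2_b) \
            * (1.0 / self.temperature)
        if self.attention_norm == "sigmoid":
            return logits.sigmoid()
        return logits.softmax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        n, c1, h, w = x.data.shape
        theta = self.attention(x)                     # (N, K)
        wflat = self.weight.reshape(self.K, self.c2 * self.c1 * self.k * self.k)
        wmix = theta @ wflat                          # (N, C2*C1*k*k), per-sample kernels
        wmix = wmix.reshape(n * self.c2, self.c1, self.k, self.k)
        xg = x.reshape(1, n * c1, h, w)
        y = conv2d(xg, wmix, None, stride=self.s, padding=self.k // 2, groups=n)
        ho, wo = y.data.shape[2], y.data.shape[3]
        return y.reshape(n, self.c2, ho, wo)


class DynConvBNAct(Module):
    """Dynamic convolution + batch norm + SiLU."""

    def __init__(self, c1, c2, k=3, s=1, K=3, temperature=1.0, rng=None):
        super().__init__()
        self.conv = DynamicConv2d(c1, c2, k, s, K=K, temperature=temperature, rng=rng)
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


# ---------------------------------------------------------------------------
# C3k2 family
# ---------------------------------------------------------------------------

def _make_conv(c1, c2, k, s, dynamic, K, rng):
    if dynamic and k >= 3:
        return DynConvBNAct(c1, c2, k, s, K=K, rng=rng)
    return ConvBNAct(c1, c2, k, s, rng=rng)


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5,
                 dynamic=False, K=3, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = _make_conv(c1, c_, k[0], 1, dynamic, K, rng)
        self.cv2 = _make_conv(c_, c2, k[1], 1, dynamic, K, rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, k=3,
                 dynamic=False, K=3, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBNAct(2 * c_, c2, 1, 1, rng=rng)
        self.m = Sequential(*(Bottleneck(c_, c_, shortcut, k=(k, k), e=1.0,
                                         dynamic=dynamic, K=K, rng=rng)
                              for _ in range(n)))

    def forward(self, x):
        return self.cv3(cat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(Module):
    """Split -> bottleneck stack -> concat -> fuse (the host C3k2 topology).

    With ``dynamic=True`` every 3x3 bottleneck convolution becomes a
    :class:`DynamicConv2d` mixture; the shape contract is unchanged.
    """

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True,
                 dynamic=False, K=3, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        if self.c < 1:
            raise ValueError("uneven channel split in C3k2")
        self.c_a = self.c_b = self.c      # may diverge after channel surgery
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1, 1, rng=rng)
        self.m = ModuleList([
            C3k(self.c, self.c, 2, shortcut, dynamic=dynamic, K=K, rng=rng) if c3k
            else Bottleneck(self.c, self.c, shortcut, k=(3, 3), e=0.5,
                            dynamic=dynamic, K=K, rng=rng)
            for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c_a]
        b = y[:, self.c_a:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(cat(outs, axis=1))


class SPPF(Module):
    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(c_ * 4, c2, 1, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(cat(y, axis=1))


# ---------------------------------------------------------------------------
# Partial self-attention (C2PSA) — part of the host baseline
# ---------------------------------------------------------------------------

class Attention(Module):
    def __init__(self, dim, num_heads=8, attn_ratio=0.5, rng=None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = ConvBNAct(dim, h, 1, act=False, rng=rng)
        self.proj = ConvBNAct(dim, dim, 1, act=False, rng=rng)
        self.pe = ConvBNAct(dim, dim, 3, 1, g=dim, act=False, rng=rng)
        self.dim = dim

    def forward(self, x):
        n, c, hh, ww = x.data.shape
        L = hh * ww
        qkv = self.qkv(x).reshape(n, self.num_heads,
                                  self.key_dim * 2 + self.head_dim, L)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim: 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = v @ attn.transpose(0, 1, 3, 2)
        out = out.reshape(n, self.dim, hh, ww)
        out = out + self.pe(v.reshape(n, self.dim, hh, ww))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c, num_heads, rng=None):
        super().__init__()
        self.attn = Attention(c, num_heads=num_heads, attn_ratio=0.5, rng=rng)
        self.ffn = Sequential(ConvBNAct(c, c * 2, 1, rng=rng),
                              ConvBNAct(c * 2, c, 1, act=False, rng=rng))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(Module):
    def __init__(self, c1, c2, n=1, e=0.5, rng=None):
        super().__init__()
        self.c = int(c1 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBNAct(2 * self.c, c1, 1, rng=rng)
        self.m = Sequential(*(PSABlock(self.c, num_heads=max(self.c // 64, 1), rng=rng)
                              for _ in range(n)))

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        return self.cv2(cat([a, self.m(b)], axis=1))


# ---------------------------------------------------------------------------
# CPCA
# ---------------------------------------------------------------------------

class CPCA(Module):
    """Channel-prior convolutional attention.

    ``F_hat = SA(CA(F) * F) * (CA(F) * F)`` with element-wise products; the
    channel map broadcasts over space.  Branch kernel sizes follow the
    published module: a 5x5 depthwise stage and strip pairs 1x7/7x1,
    1x11/11x1, 1x21/21x1 plus an identity branch, mixed by a 1x1 convolution.
    """

    STRIPS = (7, 11, 21)

    def __init__(self, c: int, reduction: int = 4, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(c // reduction, 1)
        self.mlp1 = Conv2d(c, hidden, 1, bias=True, rng=rng)
        self.mlp2 = Conv2d(hidden, c, 1, bias=True, rng=rng)
        self.dw5 = Conv2d(c, c, 5, groups=c, bias=True, rng=rng)
        strips = []
        for s in self.STRIPS:
            strips.append((Conv2d(c, c, (1, s), groups=c, bias=True, rng=rng),
                           Conv2d(c, c, (s, 1), groups=c, bias=True, rng=rng)))
        self.strips = [m for pair in strips for m in pair]
        self.mix = Conv2d(c, c, 1, bias=True, rng=rng)
        self.c = c

    # -- spec operations ---------------------------------------------------
    def channel_attention(self, f: Tensor) -> Tensor:
        """Channel map Mc in (0,1), shape (N, C, 1, 1)."""
        avg = f.mean(axis=(2, 3), keepdims=True)
        mx = f.max(axis=3, keepdims=True).max(axis=2, keepdims=True)
        shared = lambda v: self.mlp2(self.mlp1(v).relu())
        return (shared(avg) + shared(mx)).sigmoid()

    def spatial_attention(self, fc: Tensor) -> Tensor:
        """Spatial map Ms, shape-preserving (N, C, H, W)."""
        d = self.dw5(fc)
        total = d  # identity branch
        for i in range(0, len(self.strips), 2):
            total = total + self.strips[i + 1](self.strips[i](d))
        return self.mix(total)

    def forward(self, f: Tensor) -> Tensor:
        mc = self.channel_attention(f)
        fc = mc * f
        ms = self.spatial_attention(fc)
        return ms * fc


# ---------------------------------------------------------------------------
# Detection head
# ---------------------------------------------------------------------------

class DFL(Module):
    """Distribution-focal decoding: softmax over bins -> expected distance."""

    def __init__(self, reg_max: int = 16):
        super().__init__()
        self.reg_max = reg_max
        self.proj = np.arange(reg_max, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, 4*reg_max, A) -> (N, 4, A)
        n, _, a = x.data.shape
        x = x.reshape(n, 4, self.reg_max, a).softmax(axis=2)
        proj = Tensor(self.proj.reshape(1, 1, self.reg_max, 1))
        return (x * proj).sum(axis=2)


class Detect(Module):
    """Anchor-free decoupled head over three scales (strides 8/16/32)."""

    def __init__(self, nc: int, ch: Sequence[int], reg_max: int = 16, rng=None):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.nl = len(ch)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = ModuleList([
            Sequential(ConvBNAct(x, c2, 3, rng=rng), ConvBNAct(c2, c2, 3, rng=rng),
                       Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            for x in ch])
        self.cv3 = ModuleList([
            Sequential(DWConv(x, x, 3, rng=rng), ConvBNAct(x, c3, 1, rng=rng),
                       DWConv(c3, c3, 3, rng=rng), ConvBNAct(c3, c3, 1, rng=rng),
                       Conv2d(c3, nc, 1, bias=True, rng=rng))
            for x in ch])
        self.dfl = DFL(reg_max)
        self.strides = (8, 16, 32)

    def bias_init(self, img_size: int = 640) -> None:
        for i, s in enumerate(self.strides):
            self.cv2[i][-1].bias.data[:] = 1.0
            self.cv3[i][-1].bias.data[:] = math.log(5 / self.nc / (img_size / s) ** 2)

    def forward(self, feats):
        return [cat([self.cv2[i](f), self.cv3[i](f)], axis=1)
                for i, f in enumerate(feats)]
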