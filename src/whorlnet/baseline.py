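"""Baseline single-class detector skeleton (YOLOv12-n layout).

The reference architecture the improved blocks are swapped into: a CNN stem
with grouped downsampling convs, C3k2 stages, area-attention A2C2f stages at
P4/P5, an FPN/PAN neck built from A2C2f blocks, and a decoupled anchor-free
detect head with a distribution-focal box regressor. Widths/depths are the
n-scale ones (width 0.25, depth 0.5, max 1024).
"""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


class Bottleneck(nn.Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True,
                 k: tuple[int, int] = (3, 3), e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, c_, k[0])
        self.cv2 = nn.ConvBNAct(c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP block with three 1x1 transitions and k-kernel bottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 2, shortcut: bool = True,
                 e: float = 0.5, k: int = 3):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct(c1, c_, 1)
        self.cv3 = nn.ConvBNAct(2 * c_, c2, 1)
        self.m = nn.Sequential(
            *(Bottleneck(c_, c_, shortcut, (k, k), 1.0) for _ in range(n)))

    def forward(self, x):
        return self.cv3(nn.concat([self.m(self.cv1(x)), self.cv2(x)], 1))


class C3k2(nn.Module):
    """C2f-style split/concat stage whose inner blocks are bottlenecks or C3k."""

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, shortcut: bool = True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = nn.ConvBNAct((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList(
            [C3k(self.c, self.c, 2, shortcut) if c3k
             else Bottleneck(self.c, self.c, shortcut) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, :self.c], y[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(nn.concat(ys, 1))


class AreaAttention(nn.Module):
    """Multi-head attention over spatial tokens, optionally restricted to
    `area` horizontal strips, with a 7x7 depth-wise positional conv on V."""

    def __init__(self, dim: int, num_heads: int, area: int = 1):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.area = area
        self.qkv = nn.ConvBNAct(dim, dim * 3, 1, act=False)
        self.proj = nn.ConvBNAct(dim, dim, 1, act=False)
        self.pe = nn.ConvBNAct(dim, dim, 7, g=dim, act=False)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        n = h * w
        qkv = self.qkv(x)
        v_spatial = qkv[:, 2 * c:]
        tok = qkv.reshape(b, 3 * c, n).transpose(0, 2, 1)  # (b, n, 3c)
        area = self.area if n % self.area == 0 else 1
        tok = tok.reshape(b * area, n // area, 3 * c)
        q = tok[:, :, :c]
        k = tok[:, :, c:2 * c]
        v = tok[:, :, 2 * c:]
        ba, na = b * area, n // area
        hd = self.head_dim

        def heads(t):
            return t.reshape(ba, na, self.num_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(q), heads(k), heads(v)
        attn = q.matmul(k.transpose(0, 1, 3, 2)) * (hd ** -0.5)
        attn = attn.softmax(axis=-1)
        out = attn.matmul(v)  # (ba, heads, na, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, c).transpose(0, 2, 1)
        out = out.reshape(b, c, h, w)
        out = out + self.pe(v_spatial)
        return self.proj(out)


class ABlock(nn.Module):
    def __init__(self, dim: int, num_heads: int, mlp_ratio: float = 2.0,
                 area: int = 1):
        super().__init__()
        self.attn = AreaAttention(dim, num_heads, area)
        hidden = int(dim * mlp_ratio)
        self.mlp = nn.Sequential(nn.ConvBNAct(dim, hidden, 1),
                                 nn.ConvBNAct(hidden, dim, 1, act=False))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp(x)


class A2C2f(nn.Module):
    """R-ELAN stage: 1x1 in, n serial units (2 ABlocks each, or a C3k when
    attention is disabled), concat of all intermediate outputs, 1x1 out."""

    def __init__(self, c1: int, c2: int, n: int = 1, a2: bool = True,
                 area: int = 1, e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        if a2 and c_ % 32 != 0:
            raise ValueError("attention width must be a multiple of 32")
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct((1 + n) * c_, c2, 1)
        self.m = nn.ModuleList(
            [nn.Sequential(ABlock(c_, c_ // 32, 2.0, area),
                           ABlock(c_, c_ // 32, 2.0, area)) if a2
             else C3k(c_, c_, 2) for _ in range(n)])

    def forward(self, x):
        ys = [self.cv1(x)]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(nn.concat(ys, 1))


class DetectHead(nn.Module):
    """Decoupled anchor-free head: a box branch regressing 4*reg_max
    distribution bins and a class branch built from depth-wise separable
    units. Hidden widths follow the baseline's native inputs and are kept
    when the head is attached to a different neck (`hidden_ch`)."""

    def __init__(self, ch: tuple[int, ...], nc: int = 1, reg_max: int = 16,
                 hidden_ch: tuple[int, ...] | None = None):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        ref = hidden_ch if hidden_ch is not None else ch
        c2 = max(16, ref[0] // 4, reg_max * 4)
        c3 = max(ref[0], min(nc, 100))
        self.box = nn.ModuleList([
            nn.Sequential(nn.ConvBNAct(x, c2, 3), nn.ConvBNAct(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1)) for x in ch])
        self.cls = nn.ModuleList([
            nn.Sequential(nn.DWConvBNAct(x, 3), nn.ConvBNAct(x, c3, 1),
                          nn.DWConvBNAct(c3, 3), nn.ConvBNAct(c3, c3, 1),
                          nn.Conv2d(c3, nc, 1)) for x in ch])
        self.register_buffer("dfl_proj", np.arange(reg_max, dtype=np.float32))

    def forward(self, feats: dict[str, Tensor]) -> dict[str, dict[str, Tensor]]:
        out = {}
        for i, level in enumerate(("P3", "P4", "P5")):
            x = feats[level]
            out[level] = {"reg": self.box[i](x), "cls": self.cls[i](x)}
        return out
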