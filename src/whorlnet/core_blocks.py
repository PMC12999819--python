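"""Hybrid CNN-Transformer (HCT) backbone block.

The block splits its input channels between a convolutional branch (local
texture/edge features) and a transformer branch (global context) in a
configurable ratio — 1:3 by default, i.e. 75% of channels go to the
transformer — processes the two in parallel, concatenates, and fuses with a
1x1 convolution. The transformer branch is a pre-norm MHA followed by a
convolutional gated linear unit (CGLU) whose gate passes a 3x3 depth-wise
convolution and a GELU.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor


class HCTConfigError(ValueError):
    pass


@dataclass
class HCTConfig:
    """Architecture hyper-parameters of one HCT block.

    transformer_fraction: share of input channels routed to the attention
        branch (the remainder feeds the CNN branch).
    num_heads: attention heads; the transformer width is rounded down to a
        multiple of this.
    cglu_expansion: CGLU hidden width as a multiple of the transformer width.
    cnn_reduction: bottleneck width of the CNN branch as a multiple of its
        input width.
    fuse_groups: group count of the final 1x1 fusion convolution.
    """
    in_channels: int
    transformer_fraction: float = 0.75
    num_heads: int = 8
    cglu_expansion: float = 0.5
    cnn_reduction: float = 0.25
    fuse_groups: int = 1

    def __post_init__(self):
        if self.in_channels < 1:
            raise HCTConfigError(f"in_channels must be >= 1, got {self.in_channels}")
        if not 0.0 <= self.transformer_fraction <= 1.0:
            raise HCTConfigError(
                f"transformer_fraction must lie in [0, 1], got {self.transformer_fraction}")

    @property
    def transformer_channels(self) -> int:
        """round(c * fraction), snapped down to a multiple of num_heads."""
        t = round(self.in_channels * self.transformer_fraction)
        return (t // self.num_heads) * self.num_heads

    @property
    def cnn_channels(self) -> int:
        return self.in_channels - self.transformer_channels


def hct_split(x: Tensor, cfg: HCTConfig) -> tuple[Tensor, Tensor]:
    """Split channels into (cnn_part, transformer_part).

    Concatenating the parts along channels restores the input exactly.
    """
    c = x.shape[1]
    if c != cfg.in_channels:
        raise HCTConfigError(
            f"channel mismatch: config expects {cfg.in_channels}, input has {c}")
    a = cfg.cnn_channels
    return x[:, :a], x[:, a:]


class CNNBranch(nn.Module):
    """3x3 reduce -> 3x3 restore bottleneck with a residual connection."""

    def __init__(self, cfg: HCTConfig):
        super().__init__()
        a = cfg.cnn_channels
        mid = max(1, int(a * cfg.cnn_reduction))
        self.cv1 = nn.ConvBNAct(a, mid, 3)
        self.cv2 = nn.ConvBNAct(mid, a, 3)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.cv2(self.cv1(x))


class MHABlock(nn.Module):
    """Pre-norm multi-head self-attention over flattened spatial tokens.

    The query/key/value and output projections are 1x1 convolutions with
    batch norm, matching the conv units around the block.
    """

    def __init__(self, cfg: HCTConfig):
        super().__init__()
        t = cfg.transformer_channels
        if t % cfg.num_heads != 0:
            raise HCTConfigError(
                f"transformer width {t} not divisible by {cfg.num_heads} heads")
        self.num_heads = cfg.num_heads
        self.head_dim = t // cfg.num_heads
        self.norm = nn.LayerNorm(t)
        self.qkv = nn.ConvBNAct(t, 3 * t, 1, act=False)
        self.proj = nn.ConvBNAct(t, t, 1, act=False)

    def attention(self, qkv_tok: Tensor) -> Tensor:
        """qkv tokens (B, N, 3C) -> attention output tokens (B, N, C);
        exposed for the toy-oracle tests."""
        b, n, c3 = qkv_tok.shape
        c = c3 // 3
        hd, nh = self.head_dim, self.num_heads

        def split_heads(t):
            return t.reshape(b, n, nh, hd).transpose(0, 2, 1, 3)

        q = split_heads(qkv_tok[:, :, :c])
        k = split_heads(qkv_tok[:, :, c:2 * c])
        v = split_heads(qkv_tok[:, :, 2 * c:])
        attn = q.matmul(k.transpose(0, 1, 3, 2)) * (hd ** -0.5)
        attn = attn.softmax(axis=-1)
        return attn.matmul(v).transpose(0, 2, 1, 3).reshape(b, n, c)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        tok = x.reshape(b, c, h * w).transpose(0, 2, 1)
        normed = self.norm(tok).transpose(0, 2, 1).reshape(b, c, h, w)
        qkv = self.qkv(normed)
        qkv_tok = qkv.reshape(b, 3 * c, h * w).transpose(0, 2, 1)
        out = self.attention(qkv_tok)
        out = out.transpose(0, 2, 1).reshape(b, c, h, w)
        return x + self.proj(out)


class CGLUBlock(nn.Module):
    """Convolutional gated linear unit with a depth-wise 3x3 gate path.

    A single 1x1 projection produces both the value and the gate; the gate
    passes the depth-wise convolution and a GELU before the element-wise
    product, and a final 1x1 restores the width. Residual around the block.
    """

    def __init__(self, cfg: HCTConfig):
        super().__init__()
        t = cfg.transformer_channels
        h = max(1, int(t * cfg.cglu_expansion))
        self.hidden = h
        self.norm = nn.LayerNorm(t)
        self.fc1 = nn.Conv2d(t, 2 * h, 1)
        self.dw = nn.Conv2d(h, h, 3, g=h)
        self.fc2 = nn.Conv2d(h, t, 1)

    def forward(self, x: Tensor) -> Tensor:
        b, c, hh, ww = x.shape
        tok = x.reshape(b, c, hh * ww).transpose(0, 2, 1)
        tok = self.norm(tok)
        y = tok.transpose(0, 2, 1).reshape(b, c, hh, ww)
        y = self.fc1(y)
        value, gate = y[:, :self.hidden], y[:, self.hidden:]
        gate = self.dw(gate).gelu()
        return x + self.fc2(value * gate)


class HCTBlock(nn.Module):
    """split -> (CNN || MHA -> CGLU) -> concat -> 1x1 fuse."""

    def __init__(self, cfg: HCTConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.in_channels
        if cfg.cnn_channels > 0:
            self.cnn = CNNBranch(cfg)
        if cfg.transformer_channels > 0:
            self.mha = MHABlock(cfg)
            self.cglu = CGLUBlock(cfg)
        self.fuse = nn.ConvBNAct(c, c, 1, g=cfg.fuse_groups)

    def forward(self, x: Tensor) -> Tensor:
        cnn_part, tr_part = hct_split(x, self.cfg)
        outs = []
        if self.cfg.cnn_channels > 0:
            outs.append(self.cnn(cnn_part))
        if self.cfg.transformer_channels > 0:
            outs.append(self.cglu(self.mha(tr_part)))
        y = outs[0] if len(outs) == 1 else nn.concat(outs, 1)
        return self.fuse(y)


def cnn_branch(x: Tensor, cfg: HCTConfig, module: CNNBranch | None = None) -> Tensor:
    return (module or CNNBranch(cfg))(x)


def mha_block(x: Tensor, cfg: HCTConfig, module: MHABlock | None = None) -> Tensor:
    return (module or MHABlock(cfg))(x)


def cglu_block(x: Tensor, cfg: HCTConfig, module: CGLUBlock | None = None) -> Tensor:
    return (module or CGLUBlock(cfg))(x)


def hct_forward(x: Tensor, cfg: HCTConfig, module: HCTBlock | None = None) -> Tensor:
    return (module or HCTBlock(cfg))(x)
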