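"""Multi-branch multi-scale feature pyramid neck (MBMS-FPN).

Top-down/bottom-up pyramid over P3/P4/P5 at a fixed working width
(256 channels by default): efficient up-convolution blocks (EUCB) on the
top-down path, learnable fast-normalized weighted fusion at every merge
node, stride-2 convolutions on the bottom-up path, and one heterogeneous-
kernel selection block (NHKSM) per output level whose depth-wise kernel
group grows with the pyramid level ([1,3,5] at P3, [3,5,7] at P4,
[5,7,9] at P5).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .nn import Tensor

LEVELS = ("P3", "P4", "P5")


class NeckConfigError(ValueError):
    pass


class FusionError(ValueError):
    pass


@dataclass
class NeckConfig:
    neck_channels: int = 256
    kernel_groups: dict[str, list[int]] = field(default_factory=lambda: {
        "P3": [1, 3, 5], "P4": [3, 5, 7], "P5": [5, 7, 9]})
    fusion_epsilon: float = 1e-4
    emscb_expansion: float = 2.0
    # CSP transform-path fraction per level; the coarser levels take a wider
    # transform path (cheap at low resolution, where large kernels pay off)
    csp_fraction: dict[str, float] | float = field(default_factory=lambda: {
        "P3": 0.25, "P4": 0.375, "P5": 0.5})
    fuse_groups: dict[str, int] | int = field(default_factory=lambda: {
        "P3": 16, "P4": 2, "P5": 2})
    eucb_groups: int = 8
    downsample_groups: int = 16

    def level_csp(self, level: str) -> float:
        return (self.csp_fraction[level]
                if isinstance(self.csp_fraction, dict) else self.csp_fraction)

    def __post_init__(self):
        if self.fusion_epsilon <= 0:
            raise NeckConfigError("fusion_epsilon must be positive")
        for level, ks in self.kernel_groups.items():
            if any(k <= 0 or k % 2 == 0 for k in ks):
                raise NeckConfigError(
                    f"kernels for {level} must be odd and positive, got {ks}")
            if any(b <= a for a, b in zip(ks, ks[1:])):
                raise NeckConfigError(
                    f"kernel list for {level} must be strictly increasing, got {ks}")


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels by the reshape-(g, c/g)-transpose rule."""
    b, c, h, w = x.shape
    if c % groups != 0:
        raise NeckConfigError(
            f"channels {c} not divisible by shuffle groups {groups}")
    return (x.reshape(b, groups, c // groups, h, w)
            .transpose(0, 2, 1, 3, 4)
            .reshape(b, c, h, w))


def shuffle_permutation(c: int, groups: int) -> list[int]:
    """The channel index permutation channel_shuffle applies."""
    idx = list(range(c))
    per = c // groups
    return [idx[g * per + i] for i in range(per) for g in range(groups)]


class EUCB(nn.Module):
    """Efficient up-convolution: 2x nearest upsampling, 3x3 depth-wise
    conv + BN + ReLU, then a 1x1 conv matching the target width."""

    def __init__(self, in_channels: int, out_channels: int, groups: int = 1):
        super().__init__()
        self.up = nn.Upsample2x()
        self.dw = nn.DWConvBNAct(in_channels, 3, act="relu")
        self.pw = nn.ConvBNAct(in_channels, out_channels, 1, g=groups, act=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw(self.dw(self.up(x)))


def eucb_forward(x: Tensor, out_channels: int,
                 module: EUCB | None = None) -> Tensor:
    return (module or EUCB(x.shape[1], out_channels))(x)


class WeightedFusion(nn.Module):
    """Fast-normalized fusion: out = sum_i relu(w_i)/(eps + sum_j relu(w_j)) * x_i."""

    def __init__(self, n_inputs: int, eps: float = 1e-4):
        super().__init__()
        self.eps = eps
        self.weights = nn.Parameter([1.0] * n_inputs)

    def coefficients(self) -> Tensor:
        w = self.weights.relu()
        return w / (w.sum() + self.eps)

    def forward(self, inputs: list[Tensor]) -> Tensor:
        if len(inputs) != self.weights.data.size:
            raise FusionError(
                f"{self.weights.data.size} weights but {len(inputs)} inputs")
        shapes = {t.shape for t in inputs}
        if len(shapes) != 1:
            raise FusionError(f"input shapes differ: {sorted(shapes)}")
        coef = self.coefficients()
        out = inputs[0] * coef[0]
        for i, x in enumerate(inputs[1:], start=1):
            out = out + x * coef[i]
        return out


def weighted_fusion(inputs: list[Tensor], raw_weights, eps: float) -> Tensor:
    node = WeightedFusion(len(inputs), eps)
    node.weights.data[:] = raw_weights
    return node(inputs)


class DCMSCK(nn.Module):
    """Parallel depth-wise convolutions at several odd kernel sizes, each
    with BN + ReLU, summed with the identity and channel-shuffled with
    groups = number of branches."""

    def __init__(self, channels: int, kernels: list[int]):
        super().__init__()
        if not kernels:
            raise NeckConfigError("kernel list must be non-empty")
        if any(k % 2 == 0 for k in kernels):
            raise NeckConfigError(f"kernels must be odd, got {kernels}")
        # shuffle across one group per branch; if the width is not divisible
        # by the branch count (3 branches on power-of-two widths), fall back
        # to the largest divisor below it
        g = len(kernels)
        while channels % g != 0:
            g -= 1
        self.groups = max(g, 1)
        self.branches = nn.ModuleList(
            [nn.DWConvBNAct(channels, k, act="relu") for k in kernels])

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for br in self.branches:
            out = out + br(x)
        return channel_shuffle(out, self.groups)


def dcmsck_forward(x: Tensor, kernels: list[int],
                   module: DCMSCK | None = None) -> Tensor:
    return (module or DCMSCK(x.shape[1], kernels))(x)


class EMSCB(nn.Module):
    """Inverted-residual block: 1x1 expand (BN+ReLU), multi-scale depth-wise
    stage, 1x1 project (BN), residual."""

    def __init__(self, channels: int, kernels: list[int], expansion: float = 2.0):
        super().__init__()
        hidden = int(channels * expansion)
        self.expand = nn.ConvBNAct(channels, hidden, 1, act="relu")
        self.dcmsck = DCMSCK(hidden, kernels)
        self.project = nn.ConvBNAct(hidden, channels, 1, act=False)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.project(self.dcmsck(self.expand(x)))


def emscb_forward(x: Tensor, cfg: NeckConfig, level: str,
                  module: EMSCB | None = None) -> Tensor:
    if level not in cfg.kernel_groups:
        raise NeckConfigError(f"no kernel group configured for level {level}")
    if x.shape[1] != cfg.neck_channels:
        raise NeckConfigError(
            f"expected {cfg.neck_channels} channels at {level}, got {x.shape[1]}")
    mod = module or EMSCB(cfg.neck_channels, cfg.kernel_groups[level],
                          cfg.emscb_expansion)
    return mod(x)


class NHKSM(nn.Module):
    """CSP wrapper around an EMSCB: a configurable fraction of the channels
    takes the EMSCB transform path, the remainder is a shortcut; the two are
    concatenated and fused by a (grouped) 1x1 convolution."""

    def __init__(self, cfg: NeckConfig, level: str):
        super().__init__()
        if level not in cfg.kernel_groups:
            raise NeckConfigError(f"no kernel group configured for level {level}")
        c = cfg.neck_channels
        self.split = int(c * cfg.level_csp(level))
        self.emscb = EMSCB(self.split, cfg.kernel_groups[level],
                           cfg.emscb_expansion)
        fg = cfg.fuse_groups[level] if isinstance(cfg.fuse_groups, dict) \
            else cfg.fuse_groups
        self.fuse = nn.ConvBNAct(c, c, 1, g=fg)

    def forward(self, x: Tensor) -> Tensor:
        a, b = x[:, :self.split], x[:, self.split:]
        return self.fuse(nn.concat([self.emscb(a), b], 1))


def nhksm_forward(x: Tensor, cfg: NeckConfig, level: str,
                  module: NHKSM | None = None) -> Tensor:
    if x.shape[1] != cfg.neck_channels:
        raise NeckConfigError(
            f"expected {cfg.neck_channels} channels at {level}, got {x.shape[1]}")
    return (module or NHKSM(cfg, level))(x)


class MBMSFPN(nn.Module):
    """The assembled neck graph.

    Top-down: P5 -> EUCB -> fuse with P4 (node t4); t4 -> EUCB -> fuse with
    P3 -> NHKSM_P3 = out3. Bottom-up: out3 -> stride-2 conv -> fuse with t4
    -> NHKSM_P4 = out4; out4 -> stride-2 conv -> fuse with P5 lateral ->
    NHKSM_P5 = out5. Four fusion nodes, all two-input. All lateral/working/
    output widths equal neck_channels.
    """

    def __init__(self, in_channels: dict[str, int], cfg: NeckConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or NeckConfig()
        w = cfg.neck_channels
        self.lat3 = nn.ConvBNAct(in_channels["P3"], w, 1, act=False)
        self.lat4 = nn.ConvBNAct(in_channels["P4"], w, 1, act=False)
        self.lat5 = nn.ConvBNAct(in_channels["P5"], w, 1, act=False)
        self.eucb5 = EUCB(w, w, cfg.eucb_groups)
        self.eucb4 = EUCB(w, w, cfg.eucb_groups)
        self.fuse_td4 = WeightedFusion(2, cfg.fusion_epsilon)
        self.fuse_td3 = WeightedFusion(2, cfg.fusion_epsilon)
        self.fuse_bu4 = WeightedFusion(2, cfg.fusion_epsilon)
        self.fuse_bu5 = WeightedFusion(2, cfg.fusion_epsilon)
        self.down3 = nn.ConvBNAct(w, w, 3, s=2, g=cfg.downsample_groups)
        self.down4 = nn.ConvBNAct(w, w, 3, s=2, g=cfg.downsample_groups)
        self.nhksm3 = NHKSM(cfg, "P3")
        self.nhksm4 = NHKSM(cfg, "P4")
        self.nhksm5 = NHKSM(cfg, "P5")

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        shapes = [feats[k].shape for k in LEVELS]
        for (_, _, h1, w1), (_, _, h2, w2) in zip(shapes, shapes[1:]):
            if h1 != 2 * h2 or w1 != 2 * w2:
                raise NeckConfigError(
                    f"inputs are not a halving pyramid: {shapes}")
        l3, l4, l5 = (self.lat3(feats["P3"]), self.lat4(feats["P4"]),
                      self.lat5(feats["P5"]))
        t4 = self.fuse_td4([l4, self.eucb5(l5)])
        out3 = self.nhksm3(self.fuse_td3([l3, self.eucb4(t4)]))
        out4 = self.nhksm4(self.fuse_bu4([t4, self.down3(out3)]))
        out5 = self.nhksm5(self.fuse_bu5([l5, self.down4(out4)]))
        return {"P3": out3, "P4": out4, "P5": out5}


def build_neck(backbone_feats: dict[str, Tensor], cfg: NeckConfig | None = None,
               module: MBMSFPN | None = None) -> dict[str, Tensor]:
    if module is None:
        module = MBMSFPN({k: backbone_feats[k].shape[1] for k in LEVELS}, cfg)
    return module(backbone_feats)
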