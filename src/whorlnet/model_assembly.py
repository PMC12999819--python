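"""Detector assembly, variant registry, and complexity auditing.

`build_model` constructs the baseline skeleton and swaps in the three
improved components according to the variant flags: HCT blocks at the P4/P5
backbone stages, the MBMS-FPN neck, and the AMCCDH head. `count_parameters`
and `count_macs` produce the audit report used to check the architecture
against its published complexity budget.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .amccdh import AMCCDH, HeadConfig
from .baseline import A2C2f, C3k2, DetectHead
from .core_blocks import HCTBlock, HCTConfig
from .mbms_fpn import MBMSFPN, NeckConfig
from .nn import Tensor, count_macs_ctx

LEVELS = ("P3", "P4", "P5")


class StructureError(ValueError):
    pass


@dataclass
class VariantFlags:
    use_hct: bool = False
    use_mbms_fpn: bool = False
    use_amccdh: bool = False


@dataclass
class ModelConfig:
    variant_flags: VariantFlags = field(default_factory=VariantFlags)
    num_classes: int = 1
    input_size: int = 640
    width_multiple: float = 0.25
    depth_multiple: float = 0.5
    hct_p4: HCTConfig = field(default_factory=lambda: HCT_P4_DEFAULT)
    hct_p5: HCTConfig = field(default_factory=lambda: HCT_P5_DEFAULT)
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise StructureError(
                f"input_size must be divisible by 32, got {self.input_size}")
        if self.width_multiple <= 0 or self.depth_multiple <= 0:
            raise StructureError("width/depth multiples must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["variant_flags"] = VariantFlags(**d.get("variant_flags", {}))
        d["hct_p4"] = HCTConfig(**d["hct_p4"])
        d["hct_p5"] = HCTConfig(**d["hct_p5"])
        d["neck"] = NeckConfig(**d["neck"])
        d["head"] = HeadConfig(**d["head"])
        return cls(**d)


# Calibrated HCT stage configs (see docs/methods.md on the audit targets).
HCT_P4_DEFAULT = HCTConfig(in_channels=128, transformer_fraction=0.75,
                           num_heads=8, cglu_expansion=0.5, cnn_reduction=0.25,
                           fuse_groups=2)
HCT_P5_DEFAULT = HCTConfig(in_channels=256, transformer_fraction=0.75,
                           num_heads=8, cglu_expansion=0.5, cnn_reduction=0.25,
                           fuse_groups=2)


class Backbone(nn.Module):
    """YOLOv12-n backbone: grouped-conv stem, C3k2 stages, attention stages
    (A2C2f or HCT) at P4/P5. Taps P3/P4/P5 at strides 8/16/32."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        use_hct = cfg.variant_flags.use_hct
        self.stem1 = nn.ConvBNAct(3, 16, 3, s=2)
        self.stem2 = nn.ConvBNAct(16, 32, 3, s=2, g=2)
        self.stage2 = C3k2(32, 64, 1, c3k=False, e=0.25)
        self.down3 = nn.ConvBNAct(64, 64, 3, s=2, g=4)
        self.stage3 = C3k2(64, 128, 1, c3k=False, e=0.25)
        self.down4 = nn.ConvBNAct(128, 128, 3, s=2)
        self.stage4 = (HCTBlock(cfg.hct_p4) if use_hct
                       else A2C2f(128, 128, 2, a2=True, area=4))
        self.down5 = nn.ConvBNAct(128, 256, 3, s=2)
        self.stage5 = (HCTBlock(cfg.hct_p5) if use_hct
                       else A2C2f(256, 256, 2, a2=True, area=1))
        self.out_channels = {"P3": 128, "P4": 128, "P5": 256}

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        x = self.stage2(self.stem2(self.stem1(x)))
        p3 = self.stage3(self.down3(x))
        p4 = self.stage4(self.down4(p3))
        p5 = self.stage5(self.down5(p4))
        return {"P3": p3, "P4": p4, "P5": p5}


class BaselineNeck(nn.Module):
    """The baseline FPN/PAN built from A2C2f blocks and a final C3k2."""

    def __init__(self, in_channels: dict[str, int]):
        super().__init__()
        c3, c4, c5 = (in_channels[k] for k in LEVELS)
        self.up = nn.Upsample2x()
        self.td4 = A2C2f(c4 + c5, 128, 1, a2=False)
        self.td3 = A2C2f(c3 + 128, 64, 1, a2=False)
        self.down3 = nn.ConvBNAct(64, 64, 3, s=2)
        self.bu4 = A2C2f(64 + 128, 128, 1, a2=False)
        self.down4 = nn.ConvBNAct(128, 128, 3, s=2)
        self.bu5 = C3k2(128 + c5, 256, 1, c3k=True)
        self.out_channels = {"P3": 64, "P4": 128, "P5": 256}

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        p3, p4, p5 = (feats[k] for k in LEVELS)
        t4 = self.td4(nn.concat([self.up(p5), p4], 1))
        out3 = self.td3(nn.concat([self.up(t4), p3], 1))
        out4 = self.bu4(nn.concat([self.down3(out3), t4], 1))
        out5 = self.bu5(nn.concat([self.down4(out4), p5], 1))
        return {"P3": out3, "P4": out4, "P5": out5}


class WhorlDetector(nn.Module):
    """backbone -> neck -> head; raw per-level maps out."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        flags = cfg.variant_flags
        self.backbone = Backbone(cfg)
        # P3 tap of the baseline backbone is 128 wide at stage3 output per
        # the documented layout (C3k2 [512 x 0.25]).
        bb_ch = self.backbone.out_channels
        if flags.use_mbms_fpn:
            self.neck = MBMSFPN(bb_ch, cfg.neck)
            w = cfg.neck.neck_channels
            neck_ch = {k: w for k in LEVELS}
        else:
            self.neck = BaselineNeck(bb_ch)
            neck_ch = self.neck.out_channels
        if flags.use_amccdh:
            self.head = AMCCDH(neck_ch, cfg.head)
        else:
            self.head = DetectHead(tuple(neck_ch[k] for k in LEVELS),
                                   nc=cfg.num_classes,
                                   reg_max=cfg.head.reg_max,
                                   hidden_ch=(64, 128, 256))
        self.strides = (8, 16, 32)

    def forward(self, x: Tensor) -> dict[str, dict[str, Tensor]]:
        return self.head(self.neck(self.backbone(x)))


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> WhorlDetector:
    cfg = cfg or ModelConfig()
    nn.manual_seed(seed)
    return WhorlDetector(cfg)


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    per_module_params: dict[str, int]
    total_params: int
    params_millions: float
    macs_at_input: int = 0
    gflops: float = 0.0
    input_size: int | None = None

    @classmethod
    def from_counts(cls, per_module: dict[str, int], macs: int = 0,
                    input_size: int | None = None) -> "AuditReport":
        total = sum(per_module.values())
        return cls(per_module_params=per_module, total_params=total,
                   params_millions=round(total / 1e6, 3),
                   macs_at_input=macs, gflops=round(2 * macs / 1e9, 3),
                   input_size=input_size)


def count_parameters(model: WhorlDetector) -> AuditReport:
    per_module: dict[str, int] = {}
    for section in ("backbone", "neck", "head"):
        sec = getattr(model, section)
        for name, sub in sec._modules.items():
            n = sub.num_params()
            if n:
                per_module[f"{section}.{name}"] = n
        own = sum(p.data.size for p in sec._parameters.values())
        if own:
            per_module[f"{section}.<own>"] = own
    return AuditReport.from_counts(per_module)


def count_macs(model: WhorlDetector, input_size: int | None = None) -> AuditReport:
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    with count_macs_ctx() as counter:
        model(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    if was_training:
        model.train()
    report = count_parameters(model)
    report.macs_at_input = counter[0]
    report.gflops = round(2 * counter[0] / 1e9, 3)
    report.input_size = size
    return report


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _cfg(use_hct=False, use_mbms=False, use_amccdh=False, **kw) -> ModelConfig:
    return ModelConfig(variant_flags=VariantFlags(use_hct, use_mbms, use_amccdh),
                       **kw)


def variant_registry() -> dict[str, ModelConfig]:
    """Named configs mirroring the ablation grid, the per-stage transformer
    fraction sweep, and the neck width sweep."""
    reg: dict[str, ModelConfig] = {
        "baseline": _cfg(),
        "hct": _cfg(True, False, False),
        "mbms": _cfg(False, True, False),
        "amccdh": _cfg(False, False, True),
        "hct_mbms": _cfg(True, True, False),
        "hct_amccdh": _cfg(True, False, True),
        "mbms_amccdh": _cfg(False, True, True),
        "full": _cfg(True, True, True),
    }
    for f4 in (25, 50, 75):
        for f5 in (25, 50, 75):
            reg[f"hct_p4_{f4}_p5_{f5}"] = _cfg(
                True, False, False,
                hct_p4=HCTConfig(**{**asdict(HCT_P4_DEFAULT),
                                    "transformer_fraction": f4 / 100}),
                hct_p5=HCTConfig(**{**asdict(HCT_P5_DEFAULT),
                                    "transformer_fraction": f5 / 100}))
    for w in (128, 256, 512, 1024):
        reg[f"mbms_width{w}"] = _cfg(
            False, True, False,
            neck=NeckConfig(neck_channels=w))
    return reg


def get_variant(name: str) -> ModelConfig:
    reg = variant_registry()
    if name not in reg:
        raise KeyError(
            f"unknown variant {name!r}; valid names: {sorted(reg)}")
    return reg[name]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

class CheckpointError(ValueError):
    pass


def save_checkpoint(model: WhorlDetector, path, half: bool = False) -> float:
    """Serialize weights + embedded config; returns file size in MB."""
    state = model.state_dict()
    if half:
        state = {k: v.astype(np.float16) if v.dtype == np.float32 else v
                 for k, v in state.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8), **state)
    import os
    return os.path.getsize(path) / 1e6


def load_checkpoint(path, expected_nc: int | None = None) -> WhorlDetector:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg = ModelConfig.from_dict(json.loads(cfg_json))
        if expected_nc is not None and cfg.num_classes != expected_nc:
            raise CheckpointError(
                f"checkpoint has num_classes={cfg.num_classes}, expected {expected_nc}")
        model = build_model(cfg)
        state = {k: data[k].astype(np.float32) for k in data.files
                 if k != "__config__"}
        try:
            model.load_state_dict(state)
        except ValueError as exc:
            raise CheckpointError(str(exc)) from exc
    model.eval()
    return model
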