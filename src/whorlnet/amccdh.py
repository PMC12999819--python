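"""Asymmetric multi-level channel-compression detection head (AMCCDH), plus
anchor-free decoding and non-maximum suppression shared with the baseline
head.

Per pyramid level the head compresses the neck output through a level-
specific stem into a shared trunk width, then splits into three asymmetric
branches: a shallow classification branch, a medium box-regression branch
(distribution-focal bins), and a deepened IoU-quality branch built from
stacked depth-wise separable 3x3 units. The final score of a cell is the
product of the class and IoU sigmoids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

LEVELS = ("P3", "P4", "P5")


@dataclass
class Detection:
    """Normalized center-format box with score and class."""
    box: tuple[float, float, float, float]  # cx, cy, w, h in [0, 1]
    score: float
    class_id: int = 0


@dataclass
class GroundTruthBox:
    box: tuple[float, float, float, float]
    class_id: int = 0


@dataclass
class HeadConfig:
    num_classes: int = 1
    reg_max: int = 16
    strides: tuple[int, ...] = (8, 16, 32)
    # stem: level-specific conv (kernel, to stem_width), then per-branch 1x1
    # compression into asymmetric branch widths.
    stem_width: int = 32
    stem_kernel: dict[str, int] = field(default_factory=lambda: {
        "P3": 1, "P4": 1, "P5": 1})
    cls_width: int = 16
    reg_width: int = 32
    iou_width: int = 30
    cls_depth: int = 1
    reg_depth: int = 2
    iou_branch_depth: int = 2

    @property
    def compression_schedule(self) -> list[int]:
        """Shared stem-stage widths (non-increasing)."""
        return [self.stem_width,
                max(self.cls_width, self.reg_width, self.iou_width)]

    def __post_init__(self):
        sched = self.compression_schedule
        if any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError(f"compression schedule must be non-increasing: {sched}")


class DWSeparable(nn.Module):
    """3x3 depth-wise convolution followed by a 1x1 point-wise convolution."""

    def __init__(self, c: int):
        super().__init__()
        self.dw = nn.DWConvBNAct(c, 3)
        self.pw = nn.ConvBNAct(c, c, 1)

    def forward(self, x):
        return self.pw(self.dw(x))


class AMCCDH(nn.Module):
    def __init__(self, ch: dict[str, int] | tuple[int, ...],
                 cfg: HeadConfig | None = None):
        super().__init__()
        if not isinstance(ch, dict):
            ch = dict(zip(LEVELS, ch))
        self.cfg = cfg = cfg or HeadConfig()
        self.nc, self.reg_max = cfg.num_classes, cfg.reg_max
        self.stems = nn.ModuleList()
        self.cls_branches = nn.ModuleList()
        self.reg_branches = nn.ModuleList()
        self.iou_branches = nn.ModuleList()
        for level in LEVELS:
            k = cfg.stem_kernel[level]
            self.stems.append(nn.ConvBNAct(ch[level], cfg.stem_width, k))
            wc, wr, wi = cfg.cls_width, cfg.reg_width, cfg.iou_width
            self.cls_branches.append(nn.Sequential(
                nn.ConvBNAct(cfg.stem_width, wc, 1),
                *(nn.ConvBNAct(wc, wc, 3) for _ in range(cfg.cls_depth)),
                nn.Conv2d(wc, cfg.num_classes, 1)))
            self.reg_branches.append(nn.Sequential(
                nn.ConvBNAct(cfg.stem_width, wr, 1),
                *(nn.ConvBNAct(wr, wr, 3) for _ in range(cfg.reg_depth)),
                nn.Conv2d(wr, 4 * cfg.reg_max, 1)))
            self.iou_branches.append(nn.Sequential(
                nn.ConvBNAct(cfg.stem_width, wi, 1),
                *(DWSeparable(wi) for _ in range(cfg.iou_branch_depth)),
                nn.Conv2d(wi, 1, 1)))
        self.register_buffer("dfl_proj", np.arange(cfg.reg_max, dtype=np.float32))

    def forward(self, feats: dict[str, Tensor]) -> dict[str, dict[str, Tensor]]:
        out = {}
        for i, level in enumerate(LEVELS):
            s = self.stems[i](feats[level])
            out[level] = {"cls": self.cls_branches[i](s),
                          "reg": self.reg_branches[i](s),
                          "iou": self.iou_branches[i](s)}
        return out


def amccdh_forward(neck_feats: dict[str, Tensor], cfg: HeadConfig,
                   module: AMCCDH | None = None) -> dict[str, dict[str, Tensor]]:
    if module is None:
        module = AMCCDH({k: v.shape[1] for k, v in neck_feats.items()}, cfg)
    return module(neck_feats)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def dfl_expectation(reg: np.ndarray, reg_max: int) -> np.ndarray:
    """(4*reg_max, H, W) distribution logits -> (4, H, W) expected distances
    in stride units (left, top, right, bottom)."""
    r = reg.reshape(4, reg_max, *reg.shape[1:])
    r = r - r.max(axis=1, keepdims=True)
    e = np.exp(r)
    p = e / e.sum(axis=1, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float32).reshape(1, reg_max, 1, 1)
    return (p * bins).sum(axis=1)


def decode_predictions(raw: dict[str, dict[str, Tensor | np.ndarray]],
                       cfg: HeadConfig, conf_threshold: float = 0.25,
                       input_size: int | None = None) -> list[Detection]:
    """Decode per-level raw maps of one image into normalized detections.

    Box: distribution-focal expectation of the bin softmax, scaled by the
    level stride around the cell center. Score: sigmoid(cls) * sigmoid(iou)
    (or sigmoid(cls) when no IoU map is present).
    """
    dets: list[Detection] = []
    for level, stride in zip(LEVELS, cfg.strides):
        maps = raw[level]

        def arr(key):
            v = maps.get(key)
            if v is None:
                return None
            a = v.data if isinstance(v, Tensor) else np.asarray(v)
            return a[0] if a.ndim == 4 else a

        cls, reg, iou = arr("cls"), arr("reg"), arr("iou")
        _, h, w = cls.shape
        size = input_size if input_size is not None else stride * max(h, w)
        score = _sigmoid(cls)
        if iou is not None:
            score = score * _sigmoid(iou)
        dist = dfl_expectation(reg, cfg.reg_max)  # (4, h, w) stride units
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx_cell, cy_cell = (xs + 0.5) * stride, (ys + 0.5) * stride
        x1 = cx_cell - dist[0] * stride
        y1 = cy_cell - dist[1] * stride
        x2 = cx_cell + dist[2] * stride
        y2 = cy_cell + dist[3] * stride
        for ci in range(score.shape[0]):
            sel = np.argwhere(score[ci] >= conf_threshold)
            for yy, xx in sel:
                bw = (x2[yy, xx] - x1[yy, xx]) / size
                bh = (y2[yy, xx] - y1[yy, xx]) / size
                cx = (x1[yy, xx] + x2[yy, xx]) / 2 / size
                cy = (y1[yy, xx] + y2[yy, xx]) / 2 / size
                if bw <= 0 or bh <= 0:
                    continue
                dets.append(Detection(
                    box=(float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1)),
                         float(min(bw, 1.0)), float(min(bh, 1.0))),
                    score=float(score[ci, yy, xx]), class_id=int(ci)))
    return dets


def box_iou(a: tuple[float, float, float, float],
            b: tuple[float, float, float, float]) -> float:
    """IoU of two center-format boxes."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def nms(dets: list[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy score-descending suppression, class-aware."""
    order = sorted(dets, key=lambda d: -d.score)
    kept: list[Detection] = []
    for d in order:
        if all(k.class_id != d.class_id or box_iou(d.box, k.box) <= iou_threshold
               for k in kept):
            kept.append(d)
    return kept


def write_detections(dets: list[Detection], path) -> None:
    """YOLO txt with an appended score column."""
    with open(path, "w") as fh:
        for d in dets:
            cx, cy, w, h = d.box
            fh.write(f"{d.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f} {d.score:.6f}\n")
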