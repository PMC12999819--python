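"""Training and inference plumbing.

The loss and target assignment are the baseline family's machinery, not a
contribution of this package: task-aligned center-based assignment,
classification BCE, CIoU box loss, distribution-focal bin loss, and a
predicted-IoU regression target for the quality branch. Hyper-parameter
defaults follow the published training recipe (SGD, lr0 0.01, 300 epochs,
640x640, amp off, mosaic off).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .amccdh import Detection, GroundTruthBox, decode_predictions, nms as run_nms
from .metrics_eval import mean_average_precision
from .model_assembly import WhorlDetector
from .nn import Tensor

LEVELS = ("P3", "P4", "P5")
EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 300
    batch: int = 32
    img_size: int = 640
    optimizer: str = "SGD"
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    warmup_bias_lr: float = 0.1
    amp: bool = False
    close_mosaic: int = 0  # mosaic disabled throughout
    seed: int = 0
    loss_weights: dict = field(default_factory=lambda: {
        "box": 7.5, "cls": 0.5, "dfl": 1.5, "iou": 1.0})


class TrainingAbort(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# anchors and assignment
# ---------------------------------------------------------------------------

def anchor_centers(img_size: int, strides=(8, 16, 32)):
    """Per-level cell centers in pixels: list of (N_l, 2) arrays."""
    out = []
    for s in strides:
        n = img_size // s
        ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        out.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], 1))
    return out


def _iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    iw = np.clip(np.minimum(a[:, 2], b[2]) - np.maximum(a[:, 0], b[0]), 0, None)
    ih = np.clip(np.minimum(a[:, 3], b[3]) - np.maximum(a[:, 1], b[1]), 0, None)
    inter = iw * ih
    ua = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / np.maximum(ua, EPS)


def assign_targets(pred_boxes: np.ndarray, pred_cls: np.ndarray,
                   centers: np.ndarray, gts: list[GroundTruthBox],
                   img_size: int, topk: int = 10) -> dict[int, int]:
    """Task-aligned assignment: candidates are cells whose center falls
    inside the box; the top-k by (cls probability x IoU of the current
    prediction) are kept, every box claims at least its nearest cell, and a
    cell contested by two boxes goes to the higher alignment score.

    Returns {anchor_index: gt_index}.
    """
    assign: dict[int, int] = {}
    best_align: dict[int, float] = {}
    for gi, g in enumerate(gts):
        cx, cy, w, h = np.array(g.box) * img_size
        x1, y1, x2, y2 = cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2
        inside = ((centers[:, 0] > x1) & (centers[:, 0] < x2)
                  & (centers[:, 1] > y1) & (centers[:, 1] < y2))
        cand = np.nonzero(inside)[0]
        if cand.size == 0:
            cand = np.array([np.argmin(
                (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2)])
        ious = _iou_xyxy(pred_boxes[cand], np.array([x1, y1, x2, y2]))
        align = pred_cls[cand, g.class_id] * ious
        keep = cand[np.argsort(-align, kind="stable")[:topk]]
        keep_align = np.sort(align, kind="stable")[::-1][:topk]
        for ai, sc in zip(keep, keep_align):
            ai = int(ai)
            if sc > best_align.get(ai, -1.0):
                best_align[ai] = float(sc)
                assign[ai] = gi
    return assign


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(targets)
    return -(t * (p + EPS).log() + (1.0 - t) * (1.0 - p + EPS).log())


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).relu()


def _tmax(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).relu()


def _ciou_loss(px1, py1, px2, py2, gt: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Complete-IoU loss between predicted corner tensors and gt corners
    (n, 4). Also returns the detached IoU per pair."""
    g = [Tensor(gt[:, i]) for i in range(4)]
    iw = (_tmin(px2, g[2]) - _tmax(px1, g[0])).relu()
    ih = (_tmin(py2, g[3]) - _tmax(py1, g[1])).relu()
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = area_p + Tensor(area_g) - inter
    iou = inter / (union + EPS)
    # center distance over enclosing-box diagonal
    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    gcx, gcy = (gt[:, 0] + gt[:, 2]) / 2, (gt[:, 1] + gt[:, 3]) / 2
    rho2 = (pcx - Tensor(gcx)) ** 2 + (pcy - Tensor(gcy)) ** 2
    ex1, ey1 = _tmin(px1, g[0]), _tmin(py1, g[1])
    ex2, ey2 = _tmax(px2, g[2]), _tmax(py2, g[3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + EPS
    # aspect-ratio consistency
    wp, hp = px2 - px1 + EPS, py2 - py1 + EPS
    wg = gt[:, 2] - gt[:, 0]
    hg = np.maximum(gt[:, 3] - gt[:, 1], EPS)
    v = (4 / math.pi ** 2) * ((wp / hp).atan() - Tensor(np.arctan(wg / hg))) ** 2
    alpha = v.data / np.maximum(1.0 - iou.data + v.data, EPS)  # detached
    loss = 1.0 - iou + rho2 / c2 + Tensor(alpha) * v
    return loss, iou.data.copy()


def compute_loss(raw: dict[str, dict[str, Tensor]],
                 targets: list[list[GroundTruthBox]], img_size: int,
                 reg_max: int = 16, weights: dict | None = None,
                 strides=(8, 16, 32)) -> tuple[Tensor, dict[str, float]]:
    """Batch loss over raw head maps. Returns (scalar, component floats)."""
    w = weights or {"box": 7.5, "cls": 0.5, "dfl": 1.5, "iou": 1.0}
    b = raw["P3"]["cls"].shape[0]
    centers_per_level = anchor_centers(img_size, strides)
    centers = np.concatenate(centers_per_level, 0)
    stride_per_anchor = np.concatenate([
        np.full(len(c), s, dtype=np.float32)
        for c, s in zip(centers_per_level, strides)])
    nc = raw["P3"]["cls"].shape[1]
    has_iou = "iou" in raw["P3"]

    def flat(level_maps, key):
        t = level_maps[key]
        bb, cc, hh, ww = t.shape
        return t.reshape(bb, cc, hh * ww).transpose(0, 2, 1)  # (b, n, c)

    cls = nn.concat([flat(raw[l], "cls") for l in LEVELS], axis=1)
    reg = nn.concat([flat(raw[l], "reg") for l in LEVELS], axis=1)
    iou_map = nn.concat([flat(raw[l], "iou") for l in LEVELS], axis=1) if has_iou else None

    n_anchors = cls.shape[1]
    bins = np.arange(reg_max, dtype=np.float32)

    # decoded boxes (detached) for the assigner
    reg_d = reg.data.reshape(b, n_anchors, 4, reg_max)
    reg_p = np.exp(reg_d - reg_d.max(-1, keepdims=True))
    reg_p /= reg_p.sum(-1, keepdims=True)
    dist = (reg_p * bins).sum(-1) * stride_per_anchor[None, :, None]
    pred_xyxy = np.stack([centers[:, 0] - dist[:, :, 0],
                          centers[:, 1] - dist[:, :, 1],
                          centers[:, 0] + dist[:, :, 2],
                          centers[:, 1] + dist[:, :, 3]], axis=-1)
    pred_prob = 1.0 / (1.0 + np.exp(-cls.data))

    total_pos = 0
    cls_targets = np.zeros_like(cls.data)
    pos_index: list[tuple[int, int]] = []
    pos_gt: list[np.ndarray] = []
    for bi in range(b):
        assign = assign_targets(pred_xyxy[bi], pred_prob[bi], centers,
                                targets[bi], img_size)
        for ai, gi in assign.items():
            g = targets[bi][gi]
            cx, cy, bw, bh = np.array(g.box) * img_size
            cls_targets[bi, ai, g.class_id] = 1.0
            pos_index.append((bi, ai))
            pos_gt.append(np.array([cx - bw / 2, cy - bh / 2,
                                    cx + bw / 2, cy + bh / 2], dtype=np.float32))
        total_pos += len(assign)

    loss_cls = _bce(cls, cls_targets).sum() / max(total_pos, 1)
    components = {"cls": float(loss_cls.data)}
    loss = w["cls"] * loss_cls

    if total_pos:
        bis = np.array([i for i, _ in pos_index])
        ais = np.array([a for _, a in pos_index])
        gt = np.stack(pos_gt)
        s = stride_per_anchor[ais]
        cxs, cys = centers[ais, 0], centers[ais, 1]
        reg_pos = reg[bis, ais].reshape(len(ais), 4, reg_max)
        prob = reg_pos.softmax(axis=-1)
        dist_t = (prob * bins.reshape(1, 1, reg_max)).sum(axis=-1)  # (n, 4)
        spx = Tensor(s)
        px1 = Tensor(cxs) - dist_t[:, 0] * spx
        py1 = Tensor(cys) - dist_t[:, 1] * spx
        px2 = Tensor(cxs) + dist_t[:, 2] * spx
        py2 = Tensor(cys) + dist_t[:, 3] * spx
        box_l, iou_detached = _ciou_loss(px1, py1, px2, py2, gt)
        loss_box = box_l.sum() / total_pos
        components["box"] = float(loss_box.data)
        loss = loss + w["box"] * loss_box

        # distribution-focal loss on the two bins flanking the target distance
        tdist = np.stack([(cxs - gt[:, 0]) / s, (cys - gt[:, 1]) / s,
                          (gt[:, 2] - cxs) / s, (gt[:, 3] - cys) / s], 1)
        tdist = np.clip(tdist, 0, reg_max - 1 - 1e-3)
        lo = np.floor(tdist).astype(int)
        hi = lo + 1
        w_hi = tdist - lo
        w_lo = 1.0 - w_hi
        logp = (prob + EPS).log()
        n = len(ais)
        ii = np.repeat(np.arange(n), 4)
        jj = np.tile(np.arange(4), n)
        dfl = -(Tensor(w_lo.ravel()) * logp[ii, jj, lo.ravel()]
                + Tensor(w_hi.ravel()) * logp[ii, jj, hi.ravel()])
        loss_dfl = dfl.sum() / (4 * total_pos)
        components["dfl"] = float(loss_dfl.data)
        loss = loss + w["dfl"] * loss_dfl

        if iou_map is not None:
            iou_logits = iou_map[bis, ais, 0]
            iou_l = _bce(iou_logits, np.clip(iou_detached, 0, 1)).sum() / total_pos
            components["iou"] = float(iou_l.data)
            loss = loss + w["iou"] * iou_l

    if not np.isfinite(loss.data):
        raise TrainingAbort(f"non-finite loss: components={components}")
    components["total"] = float(loss.data)
    return loss, components


# ---------------------------------------------------------------------------
# optimizer and loop
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, model: nn.Module, cfg: TrainConfig):
        self.cfg = cfg
        self.params = []
        for name, p in model.named_parameters():
            decay = p.data.ndim >= 2
            bias = name.endswith("bias") or p.data.ndim == 1
            self.params.append({"p": p, "decay": decay, "bias": bias,
                                "v": np.zeros_like(p.data)})

    def lr_at(self, epoch: float) -> float:
        c = self.cfg
        frac = epoch / max(c.epochs, 1)
        return c.lr0 * (1.0 - frac) + c.lr0 * c.lrf * frac

    def step(self, epoch: float) -> None:
        c = self.cfg
        lr = self.lr_at(epoch)
        mom = c.momentum
        if epoch < c.warmup_epochs:
            t = epoch / c.warmup_epochs
            mom = c.warmup_momentum * (1 - t) + c.momentum * t
        for slot in self.params:
            p = slot["p"]
            if p.grad is None:
                continue
            g = p.grad
            if slot["decay"]:
                g = g + c.weight_decay * p.data
            plr = lr
            if epoch < c.warmup_epochs:
                t = epoch / c.warmup_epochs
                start = c.warmup_bias_lr if slot["bias"] else 0.0
                plr = start * (1 - t) + lr * t
            slot["v"] = mom * slot["v"] + g
            p.data = p.data - plr * slot["v"]


def _to_input(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float32).transpose(2, 0, 1)[None] / 255.0


def _eval_map50(model: WhorlDetector, images: list[np.ndarray],
                targets: list[list[GroundTruthBox]], img_size: int,
                conf: float = 0.05) -> float:
    model.eval()
    per_image = []
    for img, gts in zip(images, targets):
        raw = model(Tensor(_to_input(img)))
        raw_np = {l: {k: v.data for k, v in m.items()} for l, m in raw.items()}
        dets = decode_predictions(raw_np, model.cfg.head, conf, img_size)
        dets = run_nms(dets, 0.45)
        per_image.append((dets, gts))
    model.train()
    return mean_average_precision(per_image, 0.5)


def train(model: WhorlDetector, dataset: list, cfg: TrainConfig,
          eval_every: int = 10, log=None,
          stop_at_map50: float | None = None) -> dict:
    """Seeded training loop; keeps the best state by training-set mAP@0.5.

    dataset: list of LabeledImage or (pixels, boxes) pairs. Returns a history
    dict with per-epoch losses, the eval trace, and the best state dict.
    Stops early once training-set mAP@0.5 reaches `stop_at_map50`.
    """
    if not dataset:
        raise ValueError("empty dataset")
    images, targets = [], []
    for item in dataset:
        if hasattr(item, "pixels"):
            images.append(item.pixels)
            targets.append(item.boxes)
        else:
            images.append(item[0])
            targets.append(item[1])
    img_size = images[0].shape[0]
    opt = SGD(model, cfg)
    history = {"loss": [], "components": [], "map50": [], "best_map50": 0.0,
               "best_epoch": -1, "best_state": None}
    n = len(images)
    model.train()
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(cfg.seed * 100003 + epoch)
        order = rng.permutation(n)
        epoch_loss, comps_acc = 0.0, {}
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            batch = np.concatenate([_to_input(images[i]) for i in idx], 0)
            raw = model(Tensor(batch, requires_grad=False))
            loss, comps = compute_loss(raw, [targets[i] for i in idx], img_size,
                                       model.cfg.head.reg_max, cfg.loss_weights)
            model.zero_grad()
            loss.backward(np.ones_like(loss.data))
            opt.step(epoch + start / n)
            epoch_loss += float(loss.data)
            for k, v in comps.items():
                comps_acc[k] = comps_acc.get(k, 0.0) + v
        history["loss"].append(epoch_loss)
        history["components"].append(comps_acc)
        if (epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1:
            m50 = _eval_map50(model, images, targets, img_size)
            history["map50"].append((epoch, m50))
            if m50 > history["best_map50"]:
                history["best_map50"] = m50
                history["best_epoch"] = epoch
                history["best_state"] = {k: v.copy()
                                         for k, v in model.state_dict().items()}
            if log:
                log(f"epoch {epoch + 1}/{cfg.epochs} loss {epoch_loss:.3f} "
                    f"mAP50 {m50:.3f}")
            if stop_at_map50 is not None and m50 >= stop_at_map50:
                break
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def letterbox(pixels: np.ndarray, size: int,
              fill: int = 114) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Aspect-preserving resize (nearest) onto a size x size canvas.
    Returns (canvas, scale, (pad_x, pad_y))."""
    h, w = pixels.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    ys = np.clip((np.arange(nh) / scale).astype(int), 0, h - 1)
    xs = np.clip((np.arange(nw) / scale).astype(int), 0, w - 1)
    resized = pixels[ys][:, xs]
    canvas = np.full((size, size, 3), fill, dtype=pixels.dtype)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, scale, (px, py)


def predict(model: WhorlDetector, pixels: np.ndarray, conf: float = 0.25,
            iou: float = 0.45, img_size: int | None = None) -> list[Detection]:
    """letterbox -> forward -> decode -> NMS; boxes in source-image
    normalized coordinates."""
    size = img_size or model.cfg.input_size
    h, w = pixels.shape[:2]
    canvas, scale, (px, py) = letterbox(pixels, size)
    model.eval()
    raw = model(Tensor(_to_input(canvas)))
    raw_np = {l: {k: v.data for k, v in m.items()} for l, m in raw.items()}
    dets = run_nms(decode_predictions(raw_np, model.cfg.head, conf, size), iou)
    out = []
    for d in dets:
        cx, cy, bw, bh = d.box
        cx = (cx * size - px) / (scale * w)
        cy = (cy * size - py) / (scale * h)
        bw = bw * size / (scale * w)
        bh = bh * size / (scale * h)
        if bw <= 0 or bh <= 0:
            continue
        out.append(Detection(box=(float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1)),
                                  float(min(bw, 1)), float(min(bh, 1))),
                             score=d.score, class_id=d.class_id))
    return out
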