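"""Synthetic overhead maize-canopy scenes with YOLO-format labels.

The generator emulates the three challenge regimes of whorl (corn-trumpet)
field imagery: background-similar targets (whorl hue close to the canopy
hue), small targets (the camera-distance spread maps to a wide target pixel
size range), and leaf occlusion (elongated occluders drawn over targets).
It also implements the offline augmentation suite (random occlusion,
lighting shifts, random rotation/translation) and the seeded 7:2:1
train/test/val split.

Everything is a pure function of its inputs and seed: the same SceneParams
always yields a byte-identical image and label set.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .amccdh import GroundTruthBox


class GenerationError(RuntimeError):
    pass


class LabelParseError(ValueError):
    pass


@dataclass
class SceneParams:
    image_size: tuple[int, int] = (640, 640)  # (w, h)
    n_targets: int = 8
    target_size_range: tuple[int, int] = (24, 120)  # px, near/far camera spread
    background_similarity: float = 0.7  # 1.0 = whorl hue equals canopy hue
    occlusion_fraction_range: tuple[float, float] = (0.0, 0.5)
    leaf_density: float = 0.5
    seed: int = 0

    def __post_init__(self):
        w, h = self.image_size
        lo, hi = self.target_size_range
        if lo <= 0 or hi > min(w, h):
            raise ValueError(
                f"target sizes must be in (0, {min(w, h)}], got {self.target_size_range}")
        for a, b in (self.occlusion_fraction_range,):
            if not (0 <= a <= b <= 1):
                raise ValueError("occlusion fractions must satisfy 0<=lo<=hi<=1")
        if not 0 <= self.background_similarity <= 1:
            raise ValueError("background_similarity must lie in [0, 1]")


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    boxes: list[GroundTruthBox]
    meta: dict = field(default_factory=dict)


def _hsv_to_rgb(h, s, v):
    """Vectorized HSV->RGB, h in [0,1)."""
    h = (h % 1.0) * 6.0
    i = np.floor(h).astype(int)
    f = h - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    r = np.choose(i % 6, [v, q, p, p, t, v])
    g = np.choose(i % 6, [t, v, v, q, p, p])
    b = np.choose(i % 6, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def _canopy_background(w: int, h: int, rng: np.random.Generator,
                       leaf_density: float) -> np.ndarray:
    """Textured green canopy: low-frequency hue/value noise + leaf streaks."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    base = np.zeros((h, w), dtype=np.float32)
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 4.0, 2)
        ph = rng.uniform(0, 2 * np.pi, 2)
        base += rng.uniform(0.2, 0.6) * (
            np.sin(2 * np.pi * fx * xx / w + ph[0])
            * np.sin(2 * np.pi * fy * yy / h + ph[1]))
    base = (base - base.min()) / (np.ptp(base) + 1e-9)
    hue = 0.30 + 0.04 * (base - 0.5)
    val = 0.35 + 0.35 * base
    sat = 0.55 + 0.2 * (1 - base)
    img = _hsv_to_rgb(hue, sat, val)
    n_leaves = int(leaf_density * w * h / 6000)
    for _ in range(n_leaves):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.05, 0.2) * min(w, h)
        width = rng.uniform(2, 6)
        dx, dy = np.cos(ang), np.sin(ang)
        u = (xx - cx) * dx + (yy - cy) * dy
        vq = -(xx - cx) * dy + (yy - cy) * dx
        mask = (np.abs(u) < length) & (np.abs(vq) < width)
        shade = rng.uniform(-0.12, 0.18)
        img[mask] = np.clip(img[mask] + shade, 0, 1)
    return img


def _draw_whorl(img: np.ndarray, cx: float, cy: float, radius: float,
                hue_offset: float, rng: np.random.Generator) -> None:
    """Radial rosette: unfurled leaves fanning from a darker central funnel."""
    h, w = img.shape[:2]
    x0, x1 = int(max(0, cx - radius)), int(min(w, cx + radius + 1))
    y0, y1 = int(max(0, cy - radius)), int(min(h, cy + radius + 1))
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    r = np.sqrt(dx * dx + dy * dy) / radius
    theta = np.arctan2(dy, dx)
    n_leaves = rng.integers(5, 9)
    phase = rng.uniform(0, 2 * np.pi)
    petal = 0.5 + 0.5 * np.cos(n_leaves * theta + phase)
    inside = r < 1.0
    strength = inside * np.clip(1.2 - r, 0, 1) * (0.35 + 0.65 * petal)
    funnel = np.clip(1 - r / 0.25, 0, 1)
    hue = 0.30 + hue_offset
    sat = 0.5
    val = np.clip(0.45 + 0.45 * petal, 0, 1)
    rosette = _hsv_to_rgb(np.full_like(r, hue), np.full_like(r, sat), val)
    alpha = (strength * 0.9)[..., None]
    patch = img[y0:y1, x0:x1]
    patch[:] = patch * (1 - alpha) + rosette * alpha
    patch[:] = np.clip(patch - 0.35 * funnel[..., None], 0, 1)


def _draw_occluder(img: np.ndarray, cx: float, cy: float, radius: float,
                   frac: float, rng: np.random.Generator) -> None:
    """Elongated canopy-leaf strip covering ~frac of the target disk."""
    if frac <= 0:
        return
    h, w = img.shape[:2]
    x0, x1 = int(max(0, cx - radius)), int(min(w, cx + radius + 1))
    y0, y1 = int(max(0, cy - radius)), int(min(h, cy + radius + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    ang = rng.uniform(0, np.pi)
    offset = (1 - frac * 2) * radius * rng.uniform(0.3, 1.0)
    u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
    mask = u > offset - frac * radius
    leaf = _hsv_to_rgb(np.full(mask.shape, 0.30 + rng.uniform(-0.02, 0.02)),
                       np.full(mask.shape, 0.65), np.full(mask.shape, 0.40))
    patch = img[y0:y1, x0:x1]
    patch[mask] = leaf[mask]


def generate_scene(p: SceneParams) -> LabeledImage:
    """Render one labeled canopy scene; deterministic in p.seed."""
    rng = np.random.default_rng(p.seed)
    w, h = p.image_size
    img = _canopy_background(w, h, rng, p.leaf_density)
    boxes: list[GroundTruthBox] = []
    occ_fracs: list[float] = []
    placed: list[tuple[float, float, float]] = []
    # dissimilar whorls drift toward yellow-green (lower hue than canopy)
    max_hue_offset = 0.10
    hue_offset = -(1.0 - p.background_similarity) * max_hue_offset
    for _ in range(p.n_targets):
        for attempt in range(120):
            # fall back to the smallest size once placement gets tight
            radius = (p.target_size_range[0] / 2 if attempt >= 60
                      else rng.uniform(*p.target_size_range) / 2)
            cx = rng.uniform(radius, w - radius)
            cy = rng.uniform(radius, h - radius)
            if all(np.hypot(cx - px, cy - py) > 0.75 * (radius + pr)
                   for px, py, pr in placed):
                break
        else:
            raise GenerationError(
                f"could not place {p.n_targets} targets of size "
                f"{p.target_size_range} in {p.image_size}")
        placed.append((cx, cy, radius))
        _draw_whorl(img, cx, cy, radius, hue_offset, rng)
        frac = rng.uniform(*p.occlusion_fraction_range)
        _draw_occluder(img, cx, cy, radius, frac, rng)
        occ_fracs.append(float(frac))
        boxes.append(GroundTruthBox(box=(cx / w, cy / h,
                                         2 * radius / w, 2 * radius / h)))
    pixels = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    meta = {"params": asdict(p), "occlusion_fractions": occ_fracs,
            "small_target": max(p.target_size_range) < 32,
            "high_similarity": p.background_similarity >= 0.8,
            "high_occlusion": p.occlusion_fraction_range[0] >= 0.5}
    return LabeledImage(pixels=pixels, boxes=boxes, meta=meta)


def generate_benchmark_suite(n_scenes: int, seed: int = 0,
                             fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                             image_size: tuple[int, int] = (640, 640)) -> list[LabeledImage]:
    """Scene set with stated fractions of small-target / high-similarity /
    high-occlusion regimes (remainder: mixed default scenes)."""
    n_small = int(round(fractions[0] * n_scenes))
    n_sim = int(round(fractions[1] * n_scenes))
    n_occ = int(round(fractions[2] * n_scenes))
    scenes = []
    idx = 0
    # default sizes scaled to the frame so every regime packs
    hi = min(120, min(image_size) // 3)
    base = dict(target_size_range=(min(24, hi - 1), hi))
    for count, kw in ((n_small, dict(target_size_range=(12, 31), n_targets=12)),
                      (n_sim, dict(background_similarity=0.95, **base)),
                      (n_occ, dict(occlusion_fraction_range=(0.5, 0.8), **base)),
                      (n_scenes - n_small - n_sim - n_occ, base)):
        for _ in range(max(0, count)):
            scenes.append(generate_scene(SceneParams(
                image_size=image_size, seed=seed * 100003 + idx, **kw)))
            idx += 1
    return scenes


# ---------------------------------------------------------------------------
# augmentations (offline, label-aware)
# ---------------------------------------------------------------------------

def random_occlusion(img: LabeledImage, rng: np.random.Generator,
                     max_patches: int = 4,
                     patch_frac: tuple[float, float] = (0.02, 0.15)) -> LabeledImage:
    """Opaque rectangular patches; labels are kept even under full cover."""
    h, w = img.pixels.shape[:2]
    out = img.pixels.copy()
    n = int(rng.integers(0, max_patches + 1))
    for _ in range(n):
        pw = int(rng.uniform(*patch_frac) * w)
        ph = int(rng.uniform(*patch_frac) * h)
        if pw == 0 or ph == 0:
            continue
        x = int(rng.integers(0, max(1, w - pw)))
        y = int(rng.integers(0, max(1, h - ph)))
        color = rng.integers(30, 120, 3)
        out[y:y + ph, x:x + pw] = color
    return LabeledImage(out, list(img.boxes),
                        {**img.meta, "augment": "occlusion"})


def lighting_transform(img: LabeledImage, delta: float,
                       rng: np.random.Generator | None = None) -> LabeledImage:
    """Brightness shift by delta in [-1, 1] of full scale, clipped."""
    shifted = np.clip(img.pixels.astype(np.int32) + int(round(delta * 255)),
                      0, 255).astype(np.uint8)
    return LabeledImage(shifted, list(img.boxes),
                        {**img.meta, "augment": f"lighting({delta:+.3f})"})


def affine_transform(img: LabeledImage, rotation: float = 0.0,
                     translation: tuple[float, float] = (0.0, 0.0),
                     retention_threshold: float = 0.2) -> LabeledImage:
    """Rotate about the image center (degrees, CCW in image coordinates) and
    translate (pixels); boxes map through the same transform as the
    axis-aligned bounds of their transformed corners, clipped to the frame.
    Boxes retaining < retention_threshold of their area are dropped."""
    h, w = img.pixels.shape[:2]
    ang = np.deg2rad(rotation)
    ca, sa = np.cos(ang), np.sin(ang)
    cx0, cy0 = (w - 1) / 2, (h - 1) / 2
    tx, ty = translation

    # inverse nearest-neighbour warp
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    xs = xx - cx0 - tx
    ys = yy - cy0 - ty
    src_x = np.round(ca * xs + sa * ys + cx0).astype(int)
    src_y = np.round(-sa * xs + ca * ys + cy0).astype(int)
    valid = (src_x >= 0) & (src_x < w) & (src_y >= 0) & (src_y < h)
    out = np.zeros_like(img.pixels)
    out[valid] = img.pixels[src_y[valid], src_x[valid]]

    boxes: list[GroundTruthBox] = []
    for g in img.boxes:
        bcx, bcy, bw, bh = g.box
        px, py, pw_, ph_ = bcx * w, bcy * h, bw * w, bh * h
        corners = np.array([[px - pw_ / 2, py - ph_ / 2], [px + pw_ / 2, py - ph_ / 2],
                            [px - pw_ / 2, py + ph_ / 2], [px + pw_ / 2, py + ph_ / 2]])
        rel = corners - [cx0, cy0]
        fwd = np.stack([ca * rel[:, 0] - sa * rel[:, 1],
                        sa * rel[:, 0] + ca * rel[:, 1]], axis=1)
        moved = fwd + [cx0 + tx, cy0 + ty]
        x1, y1 = moved[:, 0].min(), moved[:, 1].min()
        x2, y2 = moved[:, 0].max(), moved[:, 1].max()
        cx1, cy1 = max(0.0, x1), max(0.0, y1)
        cx2, cy2 = min(float(w), x2), min(float(h), y2)
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < retention_threshold * pw_ * ph_:
            continue
        boxes.append(GroundTruthBox(box=(
            (cx1 + cx2) / 2 / w, (cy1 + cy2) / 2 / h,
            (cx2 - cx1) / w, (cy2 - cy1) / h), class_id=g.class_id))
    return LabeledImage(out, boxes,
                        {**img.meta, "augment": f"affine(rot={rotation},t={translation})"})


# ---------------------------------------------------------------------------
# dataset split and label I/O
# ---------------------------------------------------------------------------

def split_dataset(items: list, ratios: tuple[int, int, int] = (7, 2, 1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle, then largest-remainder apportionment of the ratio
    into (train, test, val)."""
    if any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be positive, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    total = sum(ratios)
    quotas = [len(items) * r / total for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(len(items) - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1
    out, start = [], 0
    for s in sizes:
        out.append([items[j] for j in order[start:start + s]])
        start += s
    return tuple(out)


def write_yolo_labels(img: LabeledImage | list[GroundTruthBox], path) -> None:
    boxes = img.boxes if isinstance(img, LabeledImage) else img
    with open(path, "w") as fh:
        for g in boxes:
            cx, cy, w, h = g.box
            fh.write(f"{g.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def read_yolo_labels(path) -> list[GroundTruthBox]:
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise LabelParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(v) for v in parts[1:5]]
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
            boxes.append(GroundTruthBox(box=tuple(vals), class_id=cid))
    return boxes


def build_dataset(out_dir, n_scenes: int = 40, multiplicity: float = 2.25,
                  seed: int = 0, image_size: tuple[int, int] = (640, 640)) -> dict:
    """Materialize an images/{train,test,val} + labels/{...} layout with a
    manifest recording seeds and regime fractions. Augmented variants are
    produced at the configured multiplicity (the source set grows by
    occlusion/lighting/affine copies, mirroring the offline pipeline)."""
    import imageio.v3 as iio
    out_dir = Path(out_dir)
    scenes = generate_benchmark_suite(n_scenes, seed, image_size=image_size)
    rng = np.random.default_rng(seed + 1)
    augmented: list[LabeledImage] = list(scenes)
    n_aug = int(round((multiplicity - 1.0) * n_scenes))
    ops = ("occlusion", "lighting", "affine")
    for i in range(max(0, n_aug)):
        src = scenes[int(rng.integers(0, len(scenes)))]
        op = ops[int(rng.integers(0, len(ops)))]
        if op == "occlusion":
            augmented.append(random_occlusion(src, rng))
        elif op == "lighting":
            augmented.append(lighting_transform(src, float(rng.uniform(-0.3, 0.3))))
        else:
            augmented.append(affine_transform(
                src, rotation=float(rng.uniform(-30, 30)),
                translation=(float(rng.uniform(-0.1, 0.1) * image_size[0]),
                             float(rng.uniform(-0.1, 0.1) * image_size[1]))))
    train, test, val = split_dataset(list(range(len(augmented))), (7, 2, 1), seed)
    manifest = {"seed": seed, "n_scenes": n_scenes, "multiplicity": multiplicity,
                "image_size": list(image_size), "splits": {}}
    for split_name, idxs in (("train", train), ("test", test), ("val", val)):
        img_dir = out_dir / "images" / split_name
        lbl_dir = out_dir / "labels" / split_name
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(lbl_dir, exist_ok=True)
        names = []
        for i in idxs:
            stem = f"scene_{i:05d}"
            iio.imwrite(img_dir / f"{stem}.png", augmented[i].pixels)
            write_yolo_labels(augmented[i], lbl_dir / f"{stem}.txt")
            names.append(stem)
        manifest["splits"][split_name] = names
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
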