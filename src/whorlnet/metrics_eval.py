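"""Detection evaluation: precision, recall, AP/mAP, and the FPS protocol.

Matching is greedy one-to-one in descending score order; a detection matches
the highest-IoU not-yet-matched ground-truth box with IoU at or above the
threshold (ties broken toward the lower ground-truth index). Precision =
TP/(TP+FP), recall = TP/(TP+FN), both 0 on an empty denominator. AP uses
all-points interpolation of the precision-recall curve; mAP averages AP over
classes (single class here, so mAP == AP), and mAP@50:95 averages over IoU
thresholds 0.50:0.05:0.95.

The FPS benchmark follows a fixed protocol: batch 1, FP32, forward pass
only (no pre/post-processing), 200 untimed warm-up iterations, then 1000
timed iterations; FPS = 1000 / mean latency in ms.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .amccdh import Detection, GroundTruthBox, box_iou

IOU_SWEEP = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_matches: list[int]  # per detection: matched gt index or -1


@dataclass
class EvalResult:
    precision: float
    recall: float
    ap_per_threshold: dict[float, float]
    map50: float
    map75: float
    map5095: float
    tp: int
    fp: int
    fn: int
    per_class_ap50: dict[int, float] = field(default_factory=dict)


def match_detections(dets: list[Detection], gts: list[GroundTruthBox],
                     iou_threshold: float) -> MatchResult:
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(gts)
    det_matches = [-1] * len(dets)
    for di in order:
        d = dets[di]
        best, best_iou = -1, -1.0
        for gi, g in enumerate(gts):
            if taken[gi] or g.class_id != d.class_id:
                continue
            iou = box_iou(d.box, g.box)
            # strictly-greater keeps the lowest gt index on ties
            if iou >= iou_threshold and iou > best_iou:
                best, best_iou = gi, iou
        if best >= 0:
            taken[best] = True
            det_matches[di] = best
    tp = sum(1 for m in det_matches if m >= 0)
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp,
                       det_matches=det_matches)


def precision_recall(counts: MatchResult) -> tuple[float, float]:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    return p, r


def _ap_from_flags(scores: np.ndarray, tp_flags: np.ndarray, n_gt: int) -> float:
    """All-points interpolated AP from score-ranked TP/FP flags."""
    if n_gt == 0 or scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp_flags[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def average_precision(per_image: list[tuple[list[Detection], list[GroundTruthBox]]],
                      iou_threshold: float = 0.5,
                      class_id: int | None = None) -> float:
    """AP over a dataset given per-image (detections, ground truths)."""
    scores, flags, n_gt = [], [], 0
    for dets, gts in per_image:
        if class_id is not None:
            dets = [d for d in dets if d.class_id == class_id]
            gts = [g for g in gts if g.class_id == class_id]
        n_gt += len(gts)
        m = match_detections(dets, gts, iou_threshold)
        for d, matched in zip(dets, m.det_matches):
            scores.append(d.score)
            flags.append(1.0 if matched >= 0 else 0.0)
    return _ap_from_flags(np.asarray(scores), np.asarray(flags), n_gt)


def mean_average_precision(per_image, iou_threshold: float = 0.5) -> float:
    classes = sorted({g.class_id for _, gts in per_image for g in gts})
    if not classes:
        return 0.0
    return float(np.mean([average_precision(per_image, iou_threshold, c)
                          for c in classes]))


def evaluate(per_image: list[tuple[list[Detection], list[GroundTruthBox]]],
             conf_threshold: float = 0.25) -> EvalResult:
    """Full evaluation: P/R at conf_threshold and IoU 0.5, plus the mAP sweep."""
    ap = {t: mean_average_precision(per_image, t) for t in IOU_SWEEP}
    tp = fp = fn = 0
    for dets, gts in per_image:
        kept = [d for d in dets if d.score >= conf_threshold]
        m = match_detections(kept, gts, 0.5)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    counts = MatchResult(tp, fp, fn, [])
    p, r = precision_recall(counts)
    return EvalResult(
        precision=p, recall=r, ap_per_threshold=ap,
        map50=ap[0.5], map75=ap[0.75],
        map5095=float(np.mean(list(ap.values()))),
        tp=tp, fp=fp, fn=fn)


def fps_benchmark(model, input_shape=(1, 3, 640, 640),
                  n_warmup: int = 200, n_iters: int = 1000) -> float:
    """Forward-only latency protocol; returns 1000 / mean-latency-ms.

    `model` is any callable taking one input array/tensor (decode and NMS are
    excluded by construction: only the forward call sits between timestamps).
    """
    if n_iters < 1:
        raise ValueError(f"n_iters must be >= 1, got {n_iters}")
    if hasattr(model, "eval"):
        model.eval()
    from .nn import Tensor
    x = Tensor(np.zeros(input_shape, dtype=np.float32))
    for _ in range(n_warmup):
        model(x)
    t0 = time.perf_counter()
    for _ in range(n_iters):
        model(x)
    t1 = time.perf_counter()
    mean_ms = (t1 - t0) * 1000.0 / n_iters
    return 1000.0 / mean_ms
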