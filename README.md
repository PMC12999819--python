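# whorlnet

Detection of maize whorls ("corn trumpets" — the funnel of unfurled leaves at
the top of a vegetative-stage corn plant) in overhead canopy imagery, for
whorl-directed precision pesticide application. The whorl is a hard target:
it is nearly the same green as the canopy around it, it is small at typical
camera distances (0.2–1 m overhead), and it is frequently occluded by leaves.

The package implements a lightweight hybrid CNN–Transformer detector built on
a YOLOv12-n-style single-class skeleton, with three replacement components:

- **HCT** (hybrid CNN–Transformer block), swapped into the P4/P5 backbone
  stages: the input channels are split 1:3 between a convolutional branch
  (local texture) and a transformer branch — pre-norm multi-head
  self-attention over spatial tokens followed by a convolutional gated linear
  unit (CGLU) — then concatenated and fused with a 1×1 convolution.
- **MBMS-FPN**, a multi-branch multi-scale neck at a fixed 256-channel width:
  efficient up-convolution blocks (EUCB) on the top-down path, learnable
  fast-normalized weighted fusion
  `O = Σᵢ [relu(ωᵢ) / (ε + Σⱼ relu(ωⱼ))] · Pᵢ` (ε = 10⁻⁴) at every merge
  node, and one CSP-wrapped heterogeneous-kernel block (NHKSM) per output
  level whose parallel depth-wise kernels grow with the level:
  [1, 3, 5] at P3, [3, 5, 7] at P4, [5, 7, 9] at P5.
- **AMCCDH**, an asymmetric channel-compression decoupled head with separate
  Cls / Reg / IoU branches; the IoU branch is deepened with stacked 3×3
  depth-wise-separable units, and the detection score is
  `sigmoid(cls) · sigmoid(iou)`.

Everything runs on a small numpy compute core with reverse-mode autodiff
(`whorlnet.nn`), so the library needs no deep-learning framework. Besides the
architecture itself the package provides: exact learnable-parameter and MAC
audits per variant (the ablation grid, a per-stage transformer-fraction
sweep, and a neck-width sweep), a COCO-style mAP evaluator with a fixed FPS
measurement protocol (batch 1, FP32, 200 warm-up + 1000 timed forward-only
iterations, FPS = 1000/mean-ms), a synthetic canopy-scene generator that
emulates the three field challenges (background similarity, small targets,
leaf occlusion) with YOLO-format labels, and a full train/predict pipeline.

## Worked example

Audit the architecture variants and train the full model on a small
synthetic scene set:

```bash
$ whorlnet build --variant full --audit --imgsz 128
variant full: 1407224 params (1.407 M)
GFLOPs @ 128: 0.174
```

```python
from whorlnet import SceneParams, generate_scene, build_model, get_variant
from whorlnet.train_infer import TrainConfig, train

data = [generate_scene(SceneParams(image_size=(128, 128), n_targets=2,
                                   target_size_range=(48, 80), seed=s))
        for s in range(8)]
cfg = get_variant("full"); cfg.input_size = 128
model = build_model(cfg, seed=0)
history = train(model, data, TrainConfig(epochs=150, batch=8, img_size=128),
                eval_every=10, stop_at_map50=0.95, log=print)
```

which prints (abridged):

```
epoch 10/150 loss 8.055 mAP50 0.000
epoch 30/150 loss 2.873 mAP50 0.000
epoch 50/150 loss 2.069 mAP50 0.221
epoch 60/150 loss 1.967 mAP50 1.000
```

The loss is the standard anchor-free detector objective (classification BCE
+ CIoU box + distribution-focal bins + IoU-quality regression); `mAP50` is
training-set mean average precision at an IoU match threshold of 0.5, so the
trace shows the model overfitting its 8 scenes — the repository's end-to-end
smoke gate — reaching a perfect training-set score by epoch 60.

Parameter audits for the component ablation (`whorlnet audit --all-variants
--json`) give, in millions of learnable parameters: baseline 2.538, HCT-only
1.992, MBMS-FPN-only 2.483, AMCCDH-only 2.207, full model 1.407 — each
single component and the three together all reduce the baseline's parameter
count, the full model by 1.13 M (45%). The full model costs 5.40 GFLOPs
(2×MACs) at 640×640.

## Layout

| module | contents |
|---|---|
| `whorlnet.nn` | numpy tensor autodiff, conv/norm/attention primitives, MAC counter |
| `whorlnet.baseline` | YOLOv12-n-style skeleton blocks (C3k2, area-attention A2C2f, detect head) |
| `whorlnet.core_blocks` | HCT block (split, CNN branch, MHA, CGLU, fuse) |
| `whorlnet.mbms_fpn` | EUCB, weighted fusion, channel shuffle, DCMSCK/EMSCB/NHKSM, neck graph |
| `whorlnet.amccdh` | decoupled head, anchor-free decoding, NMS |
| `whorlnet.model_assembly` | variant registry, builder, parameter/MAC audits, checkpoints |
| `whorlnet.metrics_eval` | matching, precision/recall, AP/mAP sweep, FPS protocol |
| `whorlnet.synthetic_data` | canopy scene generator, augmentations, 7:2:1 split, YOLO label I/O |
| `whorlnet.train_infer` | assignment, loss, SGD loop, letterbox/predict |
| `whorlnet.cli` | `whorlnet build/audit/synth/train/predict/benchmark` |

See `docs/methods.md` for the modelling choices, calibration of the
reconstructed sub-module widths, and known limitations.
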