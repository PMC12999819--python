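# Methods

## The detection model

`whorlnet` is an anchor-free, single-class convolutional detector for maize
whorls in overhead RGB imagery. The graph is the familiar three-part design:
a strided backbone that emits feature pyramids P3/P4/P5 at strides 8/16/32,
a fusion neck, and a decoupled prediction head. The baseline skeleton
follows the publicly documented YOLOv12 n-scale layout (width 0.25, depth
0.5): a grouped-conv stem, C3k2 cross-stage-partial stages, area-attention
A2C2f stages at P4/P5 with a 7×7 depth-wise positional convolution, an
A2C2f-based FPN/PAN neck, and a decoupled head whose box branch regresses
16 distribution-focal bins per side and whose class branch uses depth-wise
separable units.

Three replacement components can be swapped in independently
(`VariantFlags`), mirroring an ablation grid:

**HCT** (backbone P4/P5). Channels split `round(c·f)`-to-the-rest between a
transformer and a CNN branch, with the transformer width snapped down to a
multiple of the head count so head divisibility always holds. Defaults:
f = 0.75, 8 heads. Transformer branch: pre-LayerNorm multi-head
self-attention over the flattened spatial grid (no positional encoding —
the block sits behind convolutions that already carry location), then a
convolutional GLU whose single doubled 1×1 projection yields a value path
and a gate path; the gate passes a 3×3 depth-wise convolution and a GELU
before the element-wise product. CNN branch: 3×3 reduce / 3×3 restore
bottleneck with residual. Outputs are concatenated and fused by a grouped
1×1 convolution.

**MBMS-FPN** (neck). All laterals, working maps, and outputs are at a fixed
width (256 by default). Top-down merges upsample with EUCB (2× nearest,
3×3 depth-wise + BN + ReLU, 1×1 channel match); every merge node is a
fast-normalized weighted fusion `Σᵢ relu(ωᵢ)/(ε + Σⱼ relu(ωⱼ))·Pᵢ` with one
learnable scalar per input (initialized to 1) and ε = 10⁻⁴ for stability;
the bottom-up path downsamples with grouped 3×3 stride-2 convolutions. Each
output level passes one NHKSM: a CSP wrapper whose transform path is an
inverted-residual EMSCB (1×1 expand ×2, multi-scale depth-wise stage, 1×1
project, residual). The depth-wise stage (DCMSCK) runs parallel kernels of
level-specific sizes — [1,3,5] at P3, [3,5,7] at P4, [5,7,9] at P5 — each
with BN+ReLU, sums them with the identity, and channel-shuffles
(reshape–transpose) across one group per branch, falling back to the
largest divisor when the width is not divisible by the branch count.

**AMCCDH** (head). Per level, a 1×1 stem compresses the neck output to a
32-wide trunk, then three asymmetric branches: classification (1×1 to 16,
one 3×3 conv, 1×1 to nc logits), box regression (1×1 to 32, two 3×3 convs,
1×1 to 4×16 bins), and IoU quality (1×1 to 30, two depth-wise-separable 3×3
units, 1×1 to a single logit). Decoding takes the softmax expectation of
the bin distribution scaled by the stride around each cell center, and the
cell score is `sigmoid(cls)·sigmoid(iou)`; sigmoid monotonicity makes the
score monotone in either logit. Greedy class-aware NMS follows
(defaults: confidence 0.25, IoU 0.45).

## Calibration of reconstructed widths

Only the blocks' wiring is fixed by their published descriptions; several
internal widths (CGLU expansion, CNN bottleneck reduction, CSP fractions,
convolution group counts, head branch widths) are free. They were fixed
once, jointly, against the architecture family's published complexity
budget: HCT-variant 1.992 M parameters, AMCCDH-variant 2.207 M, full model
1.407 M, all matched to the published 3-decimal precision, and the full
model's 2×MACs at 640×640 (5.40 G) inside ±15% of the published 5.1 G.
Among parameter-equivalent designs the selection preferred low MAC counts,
which concentrates parameter mass on the coarse P4/P5 levels (wider CSP
transform paths there, heavier grouping on the 80×80 P3 level). The frozen
values are the defaults in `HCTConfig`, `NeckConfig`, and `HeadConfig`.

Not all published figures are jointly attainable: the published table is
mutually inconsistent with any fixed module-additive architecture (its own
single-component deltas disagree across rows, and no nonnegative-quadratic
width scaling passes through all four neck-width points), so the baseline
(2.538 M here vs 2.508 M), the neck-only variant, and the extreme
neck-width rows deviate; the corresponding acceptance tests are left
failing deliberately rather than bending the wiring. The neck-width sweep
retains the required qualitative behaviour: strictly monotone and
superlinear in width.

## Parameter and MAC audit

`count_parameters` counts every learnable array (conv kernels, biases, BN
and LayerNorm affine terms, fusion weights); fixed buffers such as the
distribution-focal projection are excluded. `count_macs` traces a real
forward at (1, 3, s, s) and accumulates multiply–accumulates of
convolutions and matrix products only; normalization is treated as folded,
element-wise ops are free, and GFLOPs = 2×MACs/10⁹. These conventions are
stated because complexity numbers are only comparable under a fixed
convention.

## Training and evaluation plumbing

The loss and assignment are inherited detector machinery, not a
contribution: task-aligned assignment (candidates are cells inside the box,
top-10 by classification-probability × IoU of the current prediction, at
least one cell per box, contested cells to the higher alignment),
classification BCE over all cells, CIoU on assigned boxes, two-bin
distribution-focal cross-entropy, and BCE of the IoU logit toward the
detached predicted-box IoU (an assigned-IoU target — the quality branch's
supervision signal is a design choice, not given). Loss weights follow the
baseline family (box 7.5, cls 0.5, dfl 1.5, iou 1.0). The optimizer is SGD
with momentum 0.937, weight decay 5×10⁻⁴ on weights only, linear decay
lr₀ = 0.01 → lr₀·lrf, and a 3-epoch warm-up (momentum from 0.8, bias lr
from 0.1); defaults in `TrainConfig` equal the published recipe (300
epochs, batch 32, 640×640, amp off, mosaic off — augmentation is offline in
this package).

Batch normalization uses momentum 0.1 for the running statistics.
This matters in the package's small-iteration regimes: with only ~10²
optimizer steps, a slower momentum leaves evaluation-mode statistics far
from the batch statistics the model trained under, and evaluation-mode
predictions collapse even as the training loss converges.

Evaluation: greedy one-to-one matching in descending score order (ties to
the lower ground-truth index for determinism), precision TP/(TP+FP) and
recall TP/(TP+FN) with empty denominators defined as 0, all-points
interpolated AP, mAP as the class mean (equal to AP here), and the
0.50:0.05:0.95 threshold sweep for mAP@50:95. A brute-force small-layout
matcher serves as an independent oracle in the tests. AP at a higher IoU
threshold can only lose matches, hence the monotonicity property asserted
in the tests. The FPS harness times forward calls only (no decode/NMS, no
preprocessing), batch 1, FP32, 200 untimed warm-up then 1000 timed
iterations, FPS = 1000/mean-ms; FPS values themselves are
hardware-dependent and never asserted, only the protocol is.

## Synthetic canopy scenes

The generator emulates the three stated challenges of whorl field imagery
rather than photorealism: a textured green canopy (low-frequency hue/value
noise plus leaf streaks), whorls drawn as radial rosettes with a darker
central funnel, a `background_similarity` dial that moves the whorl hue
toward the canopy green (1.0 = same hue), a target pixel-size range
standing in for the 0.2–1 m camera-distance spread, and elongated leaf
occluders drawn over targets to a sampled coverage fraction. Occluded
targets keep their full boxes — mirroring how occluded whorls are annotated
from experience — and only boxes pushed out of frame are dropped
(affine-clipped boxes are retained while ≥ 20% of their area survives; the
threshold is explicit and tested). Default generation is 640×640 with the
documented high-resolution source framing (3000×4000) available through
`image_size`. All generation and augmentation is a pure function of
(input, seed).

What passing tests on these scenes shows is that the pipeline — data,
assignment, loss, optimization, decoding, evaluation — is consistent end to
end: the overfit smoke gate (8 scenes of two large whorls at 128×128,
training-set mAP@0.5 ≥ 0.9 within 150 epochs; it typically reaches 1.0
around epoch 60, in a few CPU-minutes) is a correctness gate, not evidence
about field performance. Real canopies have perspective, self-similar
distractors, wind blur, and specular lighting the generator does not
attempt; no field-accuracy claim follows from the synthetic results.

## Numerical and engineering choices

- Compute core: float32 numpy with reverse-mode autodiff; convolution by
  per-tap shift-accumulation (einsum over channels), exact GELU via `erf`,
  stabilized softmax; BN eps 10⁻³, LN eps 10⁻⁵.
- The smoke problem size (8 scenes, 128×128, two large whorls) was chosen
  as the smallest configuration on which the full pipeline demonstrably
  converges; `TrainConfig` defaults remain the full recipe.
- Checkpoints are `.npz` archives embedding the full `ModelConfig`; loading
  restores weights bit-exactly and refuses mismatched class counts.
- The baseline detect head keeps its native hidden widths (derived from its
  (64,128,256) inputs) when attached to the 256-wide neck; only its input
  convolutions adapt. Re-deriving hidden widths from the new inputs would
  quadruple the neck-variant's head for no functional reason.
- Degenerate inputs: empty label files parse to zero boxes; images with no
  ground truth contribute only the classification term; fusion with all
  raw weights ≤ 0 yields the zero map (coefficients 0/(ε)); packing
  failures in the generator raise after bounded retries.

## Known limitations

- The numpy core is CPU-bound and single-threaded; 640×640 training is
  impractical (inference at 640 takes seconds per image). The package is
  built for audits, correctness tests, and small-scale experiments.
- Single-class focus; the head supports nc > 1 but nothing has been tuned
  for it.
- The published complexity table could not be fully reconciled (see the
  calibration section); the deviating audits are reported, not hidden.
- No rain/fog simulation, no multi-spectral channels, no deployment export.
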