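# Methods

## The detector

`yoloev` implements a single-stage, anchor-free convolutional detector of
the YOLOv8 family. The backbone is a stem of two stride-2 convolutions
followed by four stages of stride-2 convolution + C2f
(split-transform-concat with per-bottleneck concatenation), ending in fast
spatial pyramid pooling (SPPF: three cascaded 5×5 max-pools whose
concatenation equals direct pooling at 5/9/13). A top-down + bottom-up
path-aggregation neck fuses three pyramid levels (strides 8/16/32), and a
decoupled head emits, per level, `nc` class logits and `4·reg_max`
distributional box logits; boxes decode as the expectation over
`reg_max = 16` softmax bins of per-edge distances from anchor centre
points. Compound scaling follows the family convention — depth/width
multiples (0.33, 0.25), (0.33, 0.50), (0.67, 0.75) for n/s/m with width
caps 1024/1024/768 and widths rounded to multiples of 8. Block activations
are SiLU; normalization layers contribute two trainable scalars per channel
and are fused into their convolutions for FLOP accounting.

Three structural extensions are independent toggles:

- **MGEFA** after every backbone C2f (`MGEFAC2f`). Two channel-preserving
  branches — a pointwise convolution with 32-channel groups and a 3×3
  depthwise — each pass batch norm + ReLU and an **LSE** gate, are summed
  and added to the input residually. LSE pools to a 4×4 grid, slides a
  3-tap single-channel 1-D convolution *along the channel axis* of each
  pooled cell, applies a sigmoid and broadcasts the gates back over the
  map. With zero weights LSE gates are exactly 0.5 and MGEFA is exactly the
  identity; both are asserted in tests. The branch sizing makes the block
  deliberately parameter-light: 45 scalars per channel plus 8 gate
  parameters, so inserting it throughout the s backbone adds 43 k
  parameters and leaves the 0.1 M-rounded size unchanged.
- **SPPF_LSKA**. The 4-way SPPF concat (at width `2·c_top`) is multiplied by
  an attention map built from depthwise 1-D pairs — dense 7-tap
  horizontal/vertical, then 17-tap at dilation 3 — and a pointwise mix.
  Effective receptive field 7 + 3·16 = 55, in the large-kernel regime where
  separable decomposition pays off: the dense equivalent would need 55²
  taps per channel instead of 48. Separable/dense equivalence of the 1-D
  pairs is verified against a direct 2-D depthwise oracle to 1e-5.
- **P6**. The backbone P5 stage narrows to base width 768, a new stride-64
  stage (conv↓2 + C2f) at base width 1024 is appended, and SPPF(+LSKA)
  moves to the new top. The neck becomes a four-level aggregation built
  from C2 blocks — identical bottlenecks to C2f but only the two split
  halves feed the fusion convolution, which removes the per-bottleneck
  concatenation both in parameters and in compute. The head gains a fourth
  branch pair at stride 64. At s-scale the P6 level costs +6.74 M
  parameters but roughly −0.1 G at 640² because the C2 swap offsets the new
  stage's work.

Width choices for the P6 variant (768 for P5, 1024 for P6, C2 depth equal
to the other neck blocks) were calibrated against the published structural
profile of this architecture family; they are exposed in `ModelConfig`
rather than hard-coded assumptions.

## Loss

Targets are assigned by a task-aligned top-k matcher (k = 10): candidate
anchors must have their centre inside a box; the alignment metric
`score^0.5 · IoU^6` picks the 10 best per ground truth; an anchor claimed
twice goes to the higher-IoU box; target class scores are the metric
normalised so each box's best anchor receives its best IoU.

The composite loss is `7.5·box + 0.5·cls + 1.5·dfl`, each normalised by the
summed target scores. `cls` is binary cross-entropy on logits. `dfl` is
cross-entropy on the two bins bracketing each target edge distance in
stride units (clamped to `reg_max − 1 − 0.01`). The box term is **Wise-IoU**
(the v3 focusing form):

    L = r · exp(d²/c²*) · (1 − IoU),   β = (1 − IoU)* / μ,
    r = β / (δ · α^(β−δ))

with `d²` the squared centre distance, `c²` the squared enclosing-box
diagonal, `*` marking gradient detachment, and `μ` an exponential moving
average of the IoU loss updated only during training (new-batch weight
5·10⁻⁴; the first batch initialises `μ`; `μ ≤ 0` falls back to `β = 1`).
Defaults `α = 1.9`, `δ = 3` come from the focusing mechanism's reference
formulation and are exposed as configuration, not treated as facts about
any particular training run. The gain is non-monotonic with a single
interior maximum (`r = 1` at `β = δ`), vanishing for `β → 0` and `β → ∞`;
the detachment contract (no gradient through `μ`, `β`, `r` or the `c²`
denominator) is checked against a finite-difference oracle that freezes
those quantities.

A plain-IoU box term is available behind `box_variant="iou"` for ablation.

## Metrics

Greedy, class- and image-aware matching in descending confidence
(ties broken by input order, documented); each detection consumes its
best-IoU unmatched ground truth iff IoU ≥ threshold. Precision and recall
use the 0-when-undefined convention (with a warning) so curves stay
defined. AP integrates the non-increasing precision envelope over recall
(all-point interpolation, since the definition is an integral over the PR
curve); a 101-point COCO-style grid is available for cross-checks and is
verified against an independently written evaluator to 0.01 on random
fixtures. mAP averages per-class APs; classes with no ground truths are
excluded with a warning. mAP@0.5:0.95 averages over exactly the ten
thresholds 0.50:0.05:0.95, and can only be ≤ mAP@0.5.

## Profiling conventions

- Parameters: exact count of trainable scalars (the fixed DFL projection is
  a buffer). Printed "(M)" values **truncate** to one decimal — the
  convention under which this family's published structural tables are
  reproduced — via `params_m`.
- FLOPs: 2 per multiply-accumulate of every convolution on the norm-fused
  graph, batch 1, reported /10⁹ rounded to one decimal. Pooling, upsampling
  and activations are not counted, matching the profiler convention common
  in this family. Changing that convention shifts the s-scale baseline by
  roughly ±0.3 G; the sensitivity is why the acceptance checks carry a
  ±0.3 G band.

## Synthetic data

The generator emulates the *structure* of field weed imagery: a
low-frequency soil texture with elliptical foliage patches; 2–20 classes of
lobed, class-hue-coded plant blobs with log-uniform sizes (defaults
0.06–0.35 of the image edge, so most objects are small); a configurable
fraction of objects partially overpainted by later foliage
(`occlusion_rate`, default 0.3), with labels recording the pre-occlusion
extent as real annotation protocols do. Determinism is strict: one integer
seed fixes images and labels bit-for-bit.

It does **not** emulate photorealistic appearance, morphological ambiguity
between crop and weed species, lighting/weather variation, or annotation
noise. Passing the pipeline tests on these scenes therefore demonstrates
mechanical correctness (geometry, assignment, loss descent, evaluation) —
not field-level accuracy, which requires the real datasets and full-scale
training that are outside this package's scope.

Augmentation covers the standard crop/scale/flip/colour family: boxes
follow the pixels through every geometric op; crops drop boxes thinner than
2 px or below 25 % of their original area; photometric jitter works in HSV.
Magnitudes are defaults in `AugmentParams`, chosen at conventional
strengths, not asserted as facts about any reference pipeline.

## Desk-scale choices

The test suite runs everything on one CPU core in about a minute. Sizes
were chosen as the smallest that still exercise the property under test:
gradient checks on 4–6-channel tensors against central finite differences
(ε tuned to float32 cancellation); the overfitting smoke run uses 16
synthetic 64×64 scenes, the n-scale model with all toggles, batch 8,
lr 0.02 with 10-step warmup, and 200 SGD steps — it reaches mAP@0.5 ≥ 0.9
on its training images with a wide margin; class-balance statistics use 400
scenes at 3σ. Training defaults elsewhere (SGD, lr0 0.01, momentum 0.9,
300-epoch ceiling, batch 16/40) mirror the family's standard recipe and are
all overridable flags.

## Numerical notes

- float32 throughout; batch norm ε = 10⁻³, running-stat momentum 0.03.
- Convolution is im2col + matmul (einsum for grouped/depthwise); backward
  scatters one vectorised slice-add per kernel tap.
- IoU denominators are guarded by 10⁻¹²/10⁻⁹ epsilons; degenerate
  (zero-area) boxes overlap 0 with a warning.
- Max-pool padding uses −∞ so borders never win; adaptive average pooling
  uses floor/ceil bin edges.
- Weight init: Kaiming-normal convolutions, unit norm scale, zero shifts;
  head biases get the standard prior initialisation (box 1.0, class logit
  log(5/nc/grid²)). A single integer seed makes builds reproducible.

## Known limitations

- The pure-NumPy core is single-threaded BLAS-bound: a 640² forward of the
  s-scale model takes on the order of a second, so full-scale training is
  out of reach by design; the training loop exists for smoke-scale
  verification and small experiments.
- The m-scale fully extended variant counts 46.31 M parameters; published
  profiles of closely related configurations differ from this by a few
  tenths of an M, which the n/s-consistent width rules used here cannot
  absorb (any lever that moves m also moves n and s off their anchors).
- The fully extended s model computes 28.9 G at 640²; component-wise this
  is consistent with its parts, but configurations that report a *lower*
  total than their own components suggest an additional compute-saving
  change (e.g., a wider C2 swap) that would contradict the parameter
  profile and is therefore not adopted.
- NMS and matching are O(N²) per class; fine for desk-scale scenes.
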