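# Methods

## Scope and numerical substrate

The package re-creates a complete detection-and-compression stack — an
edge-prior stem, dynamic-convolution feature blocks, channel-prior attention,
progressive hybrid channel pruning, Eigen-CAM saliency, and the training and
evaluation machinery around them — on a small reverse-mode autodiff engine
written on numpy. Convolution (grouped/depthwise included), max pooling and
nearest upsampling are primitives with hand-written adjoints; everything
else is composed. All arithmetic is float32; convolutions run as im2col +
BLAS matmul. The engine is deliberately minimal: no views-with-aliasing, no
in-place autograd, a single topological backward pass. Gradient correctness
is pinned by central-difference checks in the test suite.

## Detector graphs

The baseline follows the publicly documented YOLOv11-nano layer table
(stride-2 stem convs; C3k2 stages with bottleneck expansion 0.25 in the
first two stages and C3k sub-blocks deeper; SPPF with three chained 5x5
stride-1 max pools; one C2PSA partial-self-attention stage; a PAN neck; a
decoupled anchor-free head with distribution-focal box regression,
reg_max = 16). Width multiplier 0.25, depth 0.5, single detection class.

Variant wiring:

* `c_yolo`: stem convs → CSPP blocks. The first convolution of each CSPP is
  stride 2, so two CSPPs reproduce the baseline's /4 stem resolution; the
  Prewitt and 3x3/stride-1 max-pool branches preserve that resolution so the
  channel concat is well-formed.
* `cd_yolo`: every C3k2 (backbone and neck) becomes the dynamic variant:
  each 3x3 bottleneck convolution is a K-kernel mixture. 1x1 convolutions
  stay static — they are channel mixers, and making them dynamic would blow
  the parameter budget with no spatial adaptivity to gain.
* `cdc_yolo`: one CPCA block on each of the three head-input streams
  (the per-stream placement keeps the head contract unchanged and matches
  the parameter accounting below).
* `tiny_cdc`: cdc topology at width 0.125, grayscale input, 128 px,
  reg_max = 8 — the desk profile all training tests use.

### Fixed parameters and the frozen calibration

Module knobs that the source architecture leaves open are fixed once in
`DEFAULT_KNOBS` and never varied by tests:

* dynamic-conv bank size K = 3, squeeze ratio 4, hidden width
  `max(C/4, 4)`; softmax attention with temperature `tau` (30 annealed to 1
  during training, 1 at inference) so the mixture is convex and the one-hot
  endpoints reproduce static convolution exactly;
* CPCA reduction r = 4 and strip sizes 5/7/11/21, the published module's
  own values;
* CSPP widths (branch width 8, fuse width 14 then 12 at width multiplier
  0.25). These were calibrated once against the reference accounting
  profile this implementation targets — stem replacement must leave the
  parameter total at the printed 2.58 M while adding early-stage compute,
  and the full variant must profile at ~3.64 M / 7.0 GFLOPs — and then
  frozen.

### Profiling conventions

Parameters: the headline count is the batch-norm-fused count (conv weights
plus one folded bias per BN), which is what the published tables print; the
raw count is reported alongside and equals the per-layer breakdown sum.
FLOPs: 2 x multiply-accumulates of every convolution executed at the probe
size, with activations, pooling, upsampling and attention matmuls uncounted
(the ecosystem's fused-profile convention; it reproduces the baseline's
printed 6.3 exactly). The fixed Prewitt kernels are real convolutions and
are counted.

## Blocks: choices the equations leave open

* **Prewitt magnitude** is applied depthwise to the multi-channel stem
  feature, with edge-replicate (not zero) padding: zero padding fabricates
  a frame-edge response, and the block's defining property — a constant
  input yields zero response — must hold exactly. `sqrt(g^2 + eps)` with
  eps = 1e-12 keeps the gradient finite at zero; `sqrt(eps)` is subtracted
  so constants map to exactly zero.
* **Dynamic attention normalization**: the two-layer MLP uses ReLU (as
  specified) and the final normalization is a temperature softmax. A sigmoid
  alternative would lose the convex-combination endpoint property that the
  tests pin down.
* **Channel attention max-pool ties** are averaged (mask/count backward),
  which only matters on exactly tied activations.
* Max pooling pads with -inf (the host family's semantics); the "zero
  padding" in the CSPP description is read as "size-preserving".

## Phantom generator

Each phantom is a 128 px (configurable, >= 32) grayscale slice: a head
ellipse (axes 0.46/0.40 of the frame) carrying low-frequency Gaussian
texture (scale 12 px, amplitude 0.06 around base 0.35), plus 0–3 tumor
blobs and additive Gaussian noise. A blob is an anisotropic 2-D Gaussian
with random orientation; edge blur is folded analytically into its
covariance (`cov_eff = cov + blur^2 I`) with the matching amplitude
attenuation, so the rendered profile is exact. The ground-truth box is the
axis-aligned bounding box of the half-contrast level set
(`q = 2 ln 2`), which by construction contains the blob's intensity maximum.
Placement retries (60 per blob) keep the box inside the head ellipse and
pairwise box IoU below 0.2; exhaustion raises a placement error.

Default study conditions for the desk pipeline ("easy" family): 1–2 blobs,
radii 10–18 px, contrast 0.5–0.9, blur 2 px, noise sigma 0.02. These are
chosen so that a width-0.125 model trained for ~30 epochs on ~200 images is
expected to exceed 0.9 recall — the generator emulates blurred boundaries
and textured background, but not MRI physics (bias fields, partial volume,
anatomy, scanner noise statistics), so passing tests demonstrate pipeline
correctness and trainability, not clinical performance.

Determinism: a master seed spawns per-image seeds through
`SeedSequence(master, spawn_key=(index,))`; identical (spec, seed) pairs are
bit-identical, and dataset manifests record per-image seeds and SHA-256
digests.

## Training

SGD with momentum 0.937, weight decay 5e-4, lr 0.01 cosine-annealed to 1%
(step and cosine-restart schedules available), 2 warmup epochs, batch 8 at
desk scale (16 at full scale). Augmentation per the standard recipe: 2x2
mosaic (p = 1.0), rotation ±10°, isotropic scale ±50%, horizontal flip
p = 0.5; HSV hue/saturation jitter is meaningless on single-channel data and
degrades to brightness (value) jitter with the h/s fields ignored. Boxes are
transformed through the same affine map, clipped, and dropped below 2 px.

Target assignment is a center-prior scheme: anchors (cell centers at strides
8/16/32) whose point falls inside a ground-truth box are candidates, the 9
nearest to the box center become positives, conflicts resolve by center
distance. The loss is the host family's weighted sum — BCE classification
(0.5), CIoU box (7.5), distribution-focal (1.5) — with box/DFL averaged
over positives. This is simpler than task-aligned assignment but sufficient
for the single-class, low-clutter phantom regime; it is the main
training-quality limitation at full scale.

Validation runs each epoch (confidence 0.25, class-wise NMS at IoU 0.45);
early stopping tracks validation mAP_0.5 with the configured patience and
the best checkpoint is restored, so the returned model is never worse on
the monitored metric than any epoch seen.

## Pruning

Channel spaces are registered explicitly per block type: bottleneck hiddens,
C3k hiddens (one residual-coupled group spanning cv1/cv2/bottleneck outputs
and both cv3 consumer slices), C3k2 split halves (with the m-chain output
coupled to the second half when the bottleneck has a shortcut), SPPF and
CSPP hiddens, C2PSA feed-forward hiddens, CPCA MLP hiddens, and the
detection head's hidden convolutions including depthwise pass-through
coupling. Trunk channels crossing stage boundaries and the head's output
convolutions are never pruned; global sparsity S is computed over registered
(prunable) channels only and always re-derived from current sizes.

Per step and per space: removal count `floor(M * remaining)` raised to 1
while the space is above its floor (4 channels; 2 for attention MLPs), never
crossing the floor. L1 importance sums |weights| over producing convolutions
plus |BN scale|; group importance sums squares over every *surviving*
coupled weight, including consumer columns — so it reflects the structure
that actually remains, which the standalone pseudocode oracle in the tests
replays. Defaults: s = 0.3, SC = 0.3, M = 0.05, cosine-annealed
fine-tuning; the fine-tune hook fires exactly once after the loop,
including in the degenerate s = 0 case.

The stability harness repeats prune + single fine-tune from one checkpoint
across seeds and reports the sample SD (N-1) of mAP_0.5 and mAP_0.5:0.95,
scaled x1e-3 in the printed report.

## Eigen-CAM

Computed independently on each of the three head-input streams; the
displayed map is the sum of the three *raw* (sign-fixed, rectified,
un-normalized) upsampled maps with one final min-max normalization.
Summing raw maps weights each stream by its actual activation energy;
normalizing per stream before combining (for example taking the pixel-wise
maximum of normalized maps) forces even a weakly activated coarse stream to
contribute a full-intensity hotspot and visibly de-localizes the result.
Sign is fixed by requiring a non-negative spatial sum, then ReLU and
min-max normalization — with these conventions a single-channel feature
reproduces (the normalized, rectified) feature itself.
Eigen-ties (top eigenvalue nearly degenerate) are resolved by the
deterministic symmetric solver; oracle tests exclude near-tied cases.
The localization score takes pixels strictly above the activation quantile
(falling back to >= on plateaus, and to all pixels on a flat map) and
reports the fraction inside any ground-truth box.

## Problem sizes in the shipped tests

The acceptance tests train the desk profile once — 200 phantoms
(120/40/40 split), 30 epochs — then run prune + 5-epoch fine-tune for five
seeds, reusing the first three for the recovery check and all five for the
stability report. Architecture accounting profiles at 640 px. These sizes
are the package's desk-scale study conditions; the full-scale profile
(640 px, 300 epochs) ships as configuration only.

## Known limitations

* The numpy engine is orders of magnitude slower than a GPU framework; the
  paper-scale profile is configuration, not something the suite runs.
* The assigner is center-prior top-k, not task-aligned; expected to cost
  accuracy on crowded or multi-class scenes.
* Letterboxing uses nearest-neighbour resize; phantom work is generated at
  the network size so this path is exercised mostly by the round-trip tests.
* `AP_small` follows the COCO area rule but uses a simplified ignore scheme
  (detections overlapping non-small ground truth at IoU >= 0.5 are dropped
  rather than COCO's full ignore machinery).
* Pruning covers interior channel spaces only; trunk channels would need
  cross-stage dependency closure that the registry does not model.
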