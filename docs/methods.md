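# Methods

## Problem and pipeline

The package recognizes three frame-level cattle behaviors — stand, walk,
lying — from pose alone. The design assumption is that in cluttered barn
scenes the *skeleton geometry* of the animal is a far more stable signal
than appearance, so the classifier never sees pixels: its input is a
46-channel tensor rendered from the cow16 skeleton (16 keypoints, 15 edges
forming a tree). Channel layout is fixed globally: 16 keypoint heatmaps in
schema order, then 15 two-channel part-affinity fields in schema edge
order, x-component before y-component. The behavior classes are ordered
(stand, walk, lying) everywhere — priors, logits, confusion axes — so no
axis can silently rotate between stages.

The cow16 keypoint *names* are schema data, not code. Published figures of
such schemes are schematic, so the default names (nose, forehead, neck,
withers, mid-spine, tail base, left/right front shoulder-knee-hoof,
left/right hind hip-hoof, tree rooted at the withers) are one concrete
choice; any 16-name, 15-edge tree validates and can be substituted.

## Rendering model

Geometry: keypoint-guided cropping (visible-keypoint bounding box expanded
by `margin_frac`, default 0.125, clipped to the image) followed by
aspect-preserving letterbox resizing to a square of side `input_side`
(default 368 px), then a fixed-stride mapping onto the output grid. The
default grid is 46 × 46, i.e. stride 8 at side 368 — the conventional
output stride of heatmap pose networks. The letterbox transform is exactly
invertible; padding is symmetric on the short axis.

Heatmaps use the unnormalized form `exp(-d²/σ²)` with peak 1 at the
annotation, which makes the `[0, 1]` channel invariant exact; σ defaults
to 2.0 grid pixels. PAFs store the limb's unit vector on pixels whose
projection lies on the segment and whose perpendicular distance is at most
`limb_width` (default 1.5 grid pixels — narrow enough that the four leg
limbs remain distinct at 46 × 46). With one animal per frame and 15
distinct edges, supports of the same channel can never overlap, so no
multi-instance averaging logic exists. Invisible keypoints produce
all-zero channels, as do edges with at least one invisible endpoint;
coincident limb endpoints produce zero channels with a warning. Tensors
are float32 throughout.

## Classifier

Three blocks of [3×3 conv (no bias, padding 1) → batch-norm → ReLU → 2×2
max-pool] with 64/128/256 channels, global average pooling, then
FC(256→128) → ReLU → FC(128→3), both FC layers with bias. Hidden width,
pooling and bias placement are pinned so that the architecture reproduces
both complexity figures simultaneously: 429,315 trainable scalars
(conv 26,496 + 73,728 + 294,912; BN 128 + 256 + 512; FC 32,896 + 387),
i.e. 0.43 M parameters and 429,315 × 4 / 2²⁰ = 1.64 MiB at FP32
("MB" is read as 2²⁰ bytes; only that reading matches both figures).
Global average pooling makes the network input-size agnostic (any H, W ≥ 8).

The forward and backward passes are written directly on numpy arrays:
im2col convolutions on BLAS matmuls, the standard batch-norm backward
recurrence, tie-splitting max-pool gradients, and an AdamW optimizer with
decoupled weight decay. Gradient correctness is pinned by central-difference
tests over every layer type; training is bit-deterministic for a fixed seed.

## Debiased training

Class priors `π_c = n_c / N` come from the training split only. The loss
is the cross-entropy of `softmax(z + τ·log π)` at the true label; τ
defaults to 1.0, the canonical strength in the logit-adjustment
literature (the source experiments do not state their τ). The correction
exists only inside the loss: validation, test and deployment always score
raw logits. A direction note: adding `τ·log π_c` *raises* the majority
class's training-time adjusted probability, which is what forces the
network to accumulate more evidence for majority predictions; the
equivalent inference-time view is a `−τ·log π` correction of the posterior.

Protocol: AdamW, lr 1e-3, weight decay 1e-4, batch 8, up to 40 epochs.
The returned checkpoint is the epoch argmax of validation Macro-F1 (the
primary metric; the selection criterion for the classification stage is
otherwise unstated in the source). No schedule, no augmentation.

## Ensembling and distillation

M = 5 members (default seeds 0–4) share architecture, data and protocol,
differing only in seed. Averaging happens in logit space (then softmax) —
deliberately not in probability space, which is a different estimator.
Argmax ties resolve to the lowest class index. Configuration names:
baseline (single, τ=0), A (ensemble of baselines), B (single, τ=1), AB
(ensemble of B-members). Single arms report mean ± sd over the five seeds.

Distillation minimizes `(1−λ)·CE + λ·T²·KL(p_t‖p_s)` with T = 4.0 and
λ = 0.7 (standard values; unstated in the source, surfaced in config and
recorded in every output artifact). Teacher logits are the AB member
average, precomputed once per training sample. The T² factor keeps the
soft-target gradient on the hard-loss scale — without it the KL gradient
decays like 1/T². The student trains *without* logit adjustment: the
teacher's averaged logits already encode the debiased boundary. The
student shares the single-model architecture, so its deployment cost is
exactly 1× by construction.

## Evaluation

Precision/recall/F1 are read off the 3×3 confusion matrix with the 0/0 → 0
convention in point estimates; Macro-F1 is their unweighted mean;
`key_confusion` is the stand↔walk off-diagonal total. Bootstrap CIs are
seeded percentile intervals over B = 20,000 test resamples; resamples with
an undefined metric are skipped rather than scored 0, so the convention
cannot bias the interval (BCa was considered and rejected as beyond what a
plain "bootstrap resampling" description supports). PCK normalizes by the
diagonal of the visible-truth bounding box (the reference length is
otherwise undefined for this skeleton); the choice is recorded in every
report. Display rounding is 4 decimals; JSON keeps raw values.

## Synthetic data: what it emulates and what it does not

The generator emulates side-view skeleton geometry per class: stand has
vertical legs with left/right hoof pairs horizontally aligned (stride
offset exactly 0 before jitter) and trunk centroid at 0.35–0.55 of canvas
height; walk displaces the front hoof pair by a stride of 15–35 % of trunk
length and the hind pair oppositely, knees at half amplitude; lying places
the trunk centroid at 0.70–0.90 of canvas height with hooves folded to
within 10 % of canvas height of the trunk. Every coordinate gets isotropic
Gaussian jitter; every keypoint is independently dropped to invisible with
probability `dropout_prob`. Defaults: canvas 360 × 520 (height × width —
the resized-frame convention; the other reading is a config change),
jitter sd 8 px, dropout 0.15. The jitter default is derived from the
pose-estimation quality the pipeline expects upstream: a mean PCK@0.05 of
~0.70 under bounding-box-diagonal normalization (~344 px for this
template) corresponds to a radial error σ of ~11 px, i.e. ~8 px per axis.
Split sizes and per-split class proportions default to the 2,413/323/323
structure with counts (756, 1047, 610)/(105, 186, 32)/(138, 164, 21),
apportioned by largest-remainder rounding.

Stand-vs-walk is deliberately the hardest pair (identical trunk band,
stride as the only cue), mirroring the dominant confusion mode of
frame-level recognition; a fixed two-feature rule (trunk height ratio,
hoof stride offset) recovers ≥ 95 % of labels at default jitter, which
guarantees learnable signal for end-to-end tests. What the generator does
*not* emulate: gross pose-estimator outliers (its error tail is Gaussian,
while real PCK curves are heavier-tailed), occlusion by other animals,
appearance, and temporal correlation. Two consequences for interpreting
results: passing tests certify the *mechanisms* (debiasing, ensembling,
distillation, metrics), not absolute farm-data performance; and the
synthetic task is easier than real footage — trained models reach Macro-F1
≈ 0.97 on it, so between-arm gaps are a few tenths of a percentage point
rather than the several points seen on real data, and per-replicate
orderings between closely matched arms are noise-limited (see
Limitations).

## Benchmark problem sizes

End-to-end studies run at reduced sizes chosen for single-core wall-clock:
12 × 12 grid (input side 96 at stride 8), σ = 1.0, limb width 1.0, a
narrow classifier variant (16/32/64 channels, 32 hidden units), batch 32,
4 epochs (6 on the smaller 10:1 imbalance study). The behavioral effects
exercised are scale-free; architecture-pinned quantities (parameter count,
FP32 size) always use the full default specification. One training run at
these sizes takes a few seconds on one core; the replicated
teacher/student study (60 trainings) runs in under ten minutes.

## Known limitations

* Near-ceiling synthetic difficulty compresses between-arm gaps to the
  granularity of a 323-sample test split (one sample ≈ 0.15–0.3 pp of
  Macro-F1). Aggregate effects (ensemble > single in every replicate,
  variance reduction) are reproducible; per-replicate three-way bracketing
  of the distilled student between single and teacher is noise-limited at
  this difficulty.
* Logit adjustment measurably moves recall only for classes with
  boundary mass. In the default split the rarest class (lying) is also the
  most separable, so its recall saturates at 1.0 regardless of τ; the
  debiasing effect is therefore quantified on a 10:1 imbalanced variant
  where the rare class sits on the stand-walk boundary (rare-class recall
  0.36 → 0.82 at τ = 1, 5-seed means at the benchmark problem sizes).
* Single-frame scope: no temporal modeling, no multi-animal association,
  no pose estimation from pixels (tensors are rendered from annotated or
  synthetic keypoints — the supervision-target construction of that stage).
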