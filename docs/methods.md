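# Methods

## Problem setting

Protective behaviors of dairy cattle — tail-swaying, head-shaking,
ear-flapping, leg-kicking — are brief, high-frequency motions of body
appendages, mutually exclusive with normal behavior (walking, standing,
lying).  The detection task is AVA-style spatio-temporal action detection:
given a video and candidate animal boxes on 1 Hz keyframes, classify each
box as normal or protective.  Two properties dominate the design: the
discriminative signal is motion *rate* rather than appearance, and the
classes are heavily imbalanced (the emulated corpus has a protective
fraction of roughly 0.118, i.e. 255 of 2152 labeled keyframes).

## Model

**Dual-rate backbone.**  Two bottleneck 3D-ResNet pathways (depth 50 or
101) process the same clip.  The slow pathway samples every `tau` raw
frames (default 8) at full channel width and models appearance; its
temporal convolutions are restricted to the last two stages.  The fast
pathway samples `alpha` times more frames (default 4) at `beta` times the
width (default 1/8) and models motion; it uses temporal kernels throughout.
After the stem and each of res2..res4, a FastToSlow block injects fast
features into the slow path: a `[fusion_kernel, 1, 1]` convolution with
temporal stride `alpha` (kernel 5) collapses the rate mismatch and
compresses channels by `r = 0.5`; the result is gated by ST-CBAM, lifted to
the slow width with a pointwise convolution, and added element-wise.  The
pointwise alignment is our resolution of an underdetermined point: the
addition requires equal widths but the compression step halves them.

**ST-CBAM.**  Four sequential attention stages over `[B, C, T, H, W]`
features: channel (global-average-pooled bottleneck gate), spatial
(mean+max channel maps through a `[1, 7, 7]` convolution), temporal
(spatially pooled profile through two `[3, 1, 1]` convolutions, one gate
per timestep), and joint spatio-temporal (two `[3, 1, 1]` convolutions
compressing channels to one gate per position).  The first three stages
are purely multiplicative; only the joint stage adds the block input back
(Y = X + Yt * Ast).  Bottleneck reduction defaults to 16, floor-clamped to
one channel.  We deliberately did not add the parallel max-pooling branch
of classic 2D channel attention: only average pooling feeds the channel
gate.  Every residual block of res3 and res4 is followed by an ST-CBAM on
both pathways ("STCBAMRes" blocks), toggleable per pathway.

**BAF.**  Before the head, both final-stage maps are projected to half the
slow width with pointwise convolutions (the fast projection trilinearly
resampled to the slow extents), the fast projection is motion-enhanced with
a `[3, 1, 1]` temporal convolution, and a softmax over two pooled logits
yields per-sample path weights A_s + A_f = 1 that mix the two projections.
A 3x3x3 convolution restores the slow width and the result re-enters the
slow path scaled by a learnable residual weight initialized at 0.1.  Only
the slow path is enriched; no reverse injection is defined, and the fast
map reaches the head unchanged.

**MPBHead.**  Both maps are temporally mean-pooled; per-box region features
are sampled bilinearly (one center sample per grid cell, default 7x7;
3x3 in the CPU preset) and spatially max-pooled, giving a concatenated
vector of width C_slow + C_fast (2304 at full scale).  A sigmoid
bottleneck (width C_total/4) recalibrates channels.  A two-layer MLP
(hidden 512 at full scale) produces logits calibrated as `z' = z/T + b`
before the softmax: the temperature T (default 2.0; the original work
leaves its value unstated) softens majority-class overconfidence, and the
learnable per-class bias b (zero-initialized, trained jointly by gradient
descent) shifts the boundary toward the sparse class.  The head classifies
supplied boxes only; box regression and animal detection are out of scope.

**Losses.**  All losses act on the softmax probability of the true class.
Focal loss uses a per-class balance factor (alpha for protective,
1 - alpha for normal; a symmetric variant sits behind
`alpha_per_class=False`) and focusing exponent gamma.  Weighted
cross-entropy uses per-class weights (w_normal, w_protective).  The dual
focus loss mixes them with a batch-adaptive weight
`fw = clip(L_WCE / (L_WCE + L_F), 0.3, 0.7)` computed from
gradient-detached batch means — it is a weighting schedule, not a term to
differentiate through — giving `L_DFL = fw * L_F + (1 - fw) * L_WCE`.
When both components vanish the weight is defined as 0.5 (any value gives
zero loss).  Probabilities are floored at 1e-7 before logarithms.  The
shipped hyperparameter grid crosses alpha in {0.6, 0.8}, gamma in
{2.0, 3.0} and weights 1:2 / 1:4; the default preset is (0.8, 2.0, 1:2),
the best-performing configuration in the original ablation.

## Sampling and augmentation

A pool of keyframe keys carrying at least one protective box is built once
per split.  Before each training batch, a uniform draw against trigger
probability `p` (default 0.5; the original work does not state its value)
decides whether the whole batch's keys are replaced by uniform draws from
the pool (per-sample replacement available behind a flag).  Replacement
keys are real keyframes, so clip cutting remains aligned with true video
timing.  Oversampling applies to the training loader only.

Protective clips then receive three independently triggered transforms —
color jitter (50%), color enhancement (70%, gains in [1.0, 1.5]), random
occlusion (30%, one axis-aligned mid-gray rectangle of about 10% frame
area) — with parameters drawn once per clip and shared across all frames
of both stacks, preserving motion cues.  Boxes and labels are never
modified.  Unified preprocessing resizes, rescales to [0, 1], applies
(in training mode) shared color jitter plus PCA lighting jitter along the
clip's RGB covariance axes, and centers by fixed channel statistics
(mean 0.45, std 0.225).

## Evaluation

mAP at IoU 0.5.  Matching is class-wise and per keyframe cell: descending
confidence (ties broken by input order), best-IoU ground truth claimed at
most once.  AP integrates the precision envelope over recall at every
operating point (all-point interpolation — the integral form, not the
legacy 11-point approximation).  Classes without ground truth are excluded
from the mean with a warning.  The evaluator is verified against an
independently coded brute-force evaluator on randomized instances.

## Numerical infrastructure

All tensor computation runs on a small reverse-mode autodiff engine over
float64 NumPy arrays (`cattleact.nn`), purpose-built for the rank-5
feature maps used here: broadcast arithmetic, reductions, 3D convolution
(stride-tricks windows + einsum forward, kernel-offset scatter backward),
max pooling, bilinear region sampling, and the usual layers (convolution,
linear, batch/group/layer normalization, dropout, SGD with classical
momentum and L2 weight decay).  Gradients of every primitive are tested
against central finite differences.  Everything is deterministic given the
run seed; there are no nondeterministic kernels.

Weight initialization is fan-out-scaled normal for convolutions, with the
final normalization scale of each residual block zeroed so fresh blocks
start near the identity.

**Normalization choice.**  Batch normalization follows the reference
training protocol, but with tiny batches it both destabilizes training and
— critically — lets the network read batch *composition*: minority
oversampling creates label-homogeneous batches, so a batch-statistics
shortcut can drive the training loss down without per-sample
discrimination, which then collapses at (per-sample) evaluation time.  We
observed exactly this failure in early CPU-scale runs.  The CPU preset
therefore uses group normalization in the backbone and layer normalization
in the head (batch-size-independent, identical in train and eval); the
full-scale preset keeps batch normalization.  Both are config options
(`backbone.norm`, `head.norm`).

## Synthetic corpus

The generator renders one textured "body" rectangle with an attached
darker "appendage" on a low-frequency noise background (something for
spatial attention to suppress), plus per-frame sensor noise.  Normal clips
drift slowly and coherently (0.25 Hz sway); protective clips add a
high-frequency appendage oscillation (5 Hz equivalent, 8 px amplitude) on
the same slow drift — so the class signal is motion rate, exactly the cue
the fast pathway exists for.  Keyframes are annotated at 1 Hz with the
tight body+appendage box.  Defaults: 64x64 frames at 8 fps (tests use
32x32), protective fraction 0.12 matching the emulated corpus, the number
of protective videos fixed at `round(n_videos * imbalance)` with
randomized placement.  At default settings the class-conditional mean
inter-frame pixel difference separates with effect size above 1.

What the corpus does *not* emulate: photorealistic animals, multi-animal
scenes, occlusion by pen structures, camera motion, lighting changes, or
the fine distinction among the four protective sub-actions.  Passing
desk-scale tests therefore demonstrates that the architecture, losses,
sampling and evaluation machinery are implemented correctly and that the
imbalance-handling components help when the minority class is rare and
motion-defined — not that full-scale farm-data accuracy is reproduced.

## Scale choices

The reference protocol (batch 4, learning rate 3e-5, momentum 0.9, weight
decay 1e-4, up to 100 epochs, 224x224 inputs, depth 50/101 at full width)
ships as the `full_scale` preset.  The test-suite and worked examples use
the `tiny` preset — one block per stage, 8-channel stem, T_slow = 4,
32x32 inputs, learning rate 0.02, a handful of epochs — chosen as the
smallest configuration that preserves every architectural element (both
pathways, all four lateral fusions, STCBAMRes stages, BAF, the calibrated
head).  Its two reference experiments: (1) memorization sanity — 8 training clips
(5 videos of 16 frames), 30 epochs at batch 2 with cosine-decayed learning
rate and stochastic augmentation disabled, must reach training mAP >= 0.95
(the decay matters: with a constant rate the final model oscillates around
the optimum and single-clip flips are common at this scale); (2) imbalance
ordering — on a 50-video corpus of 16-frame videos at protective fraction
0.12, mean held-out protective-class AP over 3 training seeds with the
dual loss plus oversampling versus plain cross-entropy with uniform
sampling (4 epochs, the sampling-starved regime where minority exposure
matters).  Both experiments use videos long enough that the clip window
contains real motion rather than mostly edge-replicated padding.

The imbalance ordering deserves a candid caveat.  With exactly two
mutually exclusive classes the softmax gives p_protective = 1 − p_normal,
so whatever the majority class teaches about the discriminative feature
transfers in full to minority *ranking*, and average precision is
invariant to the monotone score shifts that class-bias corrections
provide.  This removes much of the headroom that imbalance-aware
machinery has on real multi-action farm data.  In our own diagnostics the
timing-aware oversampling alone consistently raises protective AP over
uniform sampling, while stacking it with the dual loss's protective
weighting can overcompensate (protective gradient share well above one
half) — the same overcompensation effect that makes 1:2 class weights
outperform 1:4 in the loss ablation this package reproduces as presets.
Desk-scale outcomes are also bimodal (a run either learns the motion cue
or scores near the prevalence floor), so three-seed means are noisy.  The
acceptance script therefore reports the dual-loss, plain-cross-entropy,
and oversampled-cross-entropy arms side by side rather than a single
verdict.

One desk-scale artifact deserves note: at 32x32 the default occlusion
patch (10% of frame area) often covers the entire appendage — the very
feature that defines the protective class — turning augmentation into
label noise.  The tiny preset therefore shrinks the patch to 3% of frame
area while keeping the 30% activation probability; at the native
1280x720 resolution a 10% occluder models *partial* occlusion as
intended, and the default config keeps it.

## Known limitations

- The engine is CPU/NumPy; full-scale training is out of reach by design.
- ROI sampling uses one bilinear sample per output cell rather than the
  4-point average of the reference implementation of ROIAlign.
- "Color enhancement" and "color jitter" magnitudes are configurable
  choices; the original work specifies only their activation
  probabilities.
- The VIA converter expects frame geometry in the export's file
  attributes and frame indices in filenames (`<video>_<frame>.jpg`);
  other VIA layouts need pre-processing.
- AP with very few ground-truth boxes (as in the desk-scale test split) is
  coarse-grained; the directional experiment averages seeds to compensate.
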