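# Methods

## Problem and approach

`appleseg` segments surface defects on apples imaged in up to four
spectral bands (R, G, B at 450/500 nm plus a near-infrared band around
750–800 nm; 8-bit per band, nominally 430×560 pixels). The output is a
per-pixel defect probability map. Three ingredients make up the method:

1. a **lightweight U-shaped encoder–decoder network** built from
   inverted-residual bottlenecks, compact enough for quasi-real-time
   CPU inference and able to process full-resolution images without
   resizing or cropping;
2. a **copy-paste data-synthesis procedure** that transplants annotated
   defect regions from defective apples onto healthy apples during
   training, increasing defect diversity on small datasets;
3. the **Focal Tversky Loss** as the training objective, handling the
   severe class imbalance between defect pixels and the apple surface.

## Network

The encoder stem is a 3×3 stride-2 convolution that raises the channel
count and halves the spatial size. A *noise-reduction* block follows: a
3×3 depth-wise convolution, then a point-wise convolution halving the
channel count. The block carries a shortcut; because the point-wise
convolution changes the channel count, a plain identity cannot bridge
it, so the shortcut is a linear 1×1 projection (the standard residual
convention for shape-changing blocks).

The body is three bottleneck stages. Each bottleneck expands channels
point-wise by a factor `t`, filters with a 3×3 depth-wise convolution
(stride 2 in the first block of a stage, stride 1 with an identity
residual otherwise), and projects back down point-wise. Blocks per
stage are non-decreasing with depth — (2, 3, 4) by default — so coarse
structures (bruise-sized) and fine ones (russet, scald) are both
represented. Batch normalization and ReLU6 follow every convolution
except the head.

The decoder upsamples bilinearly level by level and fuses with a 3×3
stride-1 pad-1 convolution. Two skip policies exist:

* `noise_block_only` (default): the only encoder→decoder connection
  passes the noise-reduction block's output to the matching-resolution
  decoder level;
* `full_unet`: every encoder stage output is concatenated at its
  matching decoder level (kept for ablation; the published description
  of the decoder is ambiguous between the two readings, so both are
  implemented behind a switch rather than guessing the intent).

A 1×1 convolution plus sigmoid produces the defect probability at half
resolution, which is bilinearly upsampled to the input size. For
arbitrary input sizes, images are zero-padded bottom/right to the next
multiple of `2^levels` (levels = 1 + number of stages, 4 by default)
and the output is cropped back, so prediction is exactly
shape-preserving.

**Default widths.** The published architecture figure fixes the layer
roles but its exact channel numbers are not recoverable from text, so
the defaults here — stem 48, noise reduction to 24, stages
(32, 64, 128) with t = 6, decoder (80, 48, 24) — were chosen once to
satisfy every textual constraint and to land in the published compact
regime of about 7 GFLOPs for a 4-band 430×560 input (the package's
estimator reports 7.70 G; the FLOPs convention is 2 ×
multiply-accumulates summed over all convolutions at their true
spatial resolutions, with batch norm, activations, biases and
upsampling excluded). All widths are configuration-exposed.

**Compute engine.** The network runs on the package's own numpy
reverse-mode autodiff engine (`appleseg.nn`): grouped/depth-wise
convolution via im2col and einsum, batch normalization with batch and
running statistics, ReLU6, sigmoid, bilinear upsampling, concatenation
and residual addition, each with an analytic backward pass verified
against central finite differences to ~1e-9. Weights are initialized
Kaiming-uniform (fan-in) from a seeded generator; batch-norm scale 1,
shift 0.

## Loss

For one image with predicted defect probabilities `p_i` and binary
ground truth `g_i`,

    TI  = (Σ p·g + ε) / (Σ p·g + α Σ (1−p)·g + (1−α) Σ p·(1−g) + ε)
    FTL = (1 − TI)^(1/γ)

with defaults α = 0.5, γ = 0.75, ε = 1e-6. Only the defect class is
scored (the task is binary with a sigmoid head; adding the complement
class would double-count — an `include_background` flag restores the
two-term sum for comparison). ε is not stated in the source
formulation; 1e-6 keeps the empty-defect case (`TI = ε/ε = 1`, loss 0
for a correct all-negative prediction) numerically exact. Larger α
weights the false-negative mass more, making training recall-oriented;
note the Tversky denominator implies TI is strictly decreasing in α
only while the FN mass exceeds the FP mass. Batch loss is the mean of
per-image losses; the analytic gradient w.r.t. `p` is injected at the
sigmoid output.

## Training protocol

Adam (lr 1e-4, β = (0.9, 0.999), ε = 1e-8, weight decay 0), learning
rate multiplied by 0.7 every 10 epochs (closed form
`lr·0.7^⌊e/10⌋`), at most 100 epochs with early stopping after 15
epochs without a strict validation-loss improvement (the improvement
tolerance is not specified anywhere authoritative; strict decrease was
chosen). The best-validation weights are restored. Splits are
50% train / 17% validation / 33% test, stratified by the healthy flag
and macro defect class; global counts follow `round(n·fraction)` with
the remainder in train.

Per epoch, every *healthy* training image passes through the synthesis
hook (the procedure pastes defects onto healthy apples, so defective
images pass straight through), firing independently with probability
P = 0.8; then every training image receives classic augmentation: a
50% outer gate, inside which horizontal flip, vertical flip and a
rotation by a continuous uniform angle in [0°, 90°] each fire with
independent probability 0.5. Whether the published rotation is
continuous or a discrete 90° choice is ambiguous; continuous is the
default and configurable. Validation and test images are never
synthesized or augmented. The defective pool for synthesis is the
training split only, so no test defect leaks into training.

For small phantom images (128×128) the package uses a scaled preset
(`phantom_train_config`): batch size 16 and lr 1e-3, compensating the
few optimizer steps per epoch at this problem size; the full-resolution
preset keeps the protocol values above (batch size 4 is a
memory-bound choice, as the batch size is unspecified upstream).

## Copy-paste synthesis

Six setups toggle the defect count and the transforms (1: none;
2: one defect, no transform; 3: one defect + rotation; 4: one defect +
rotation + warp; 5: 1–3 defects + rotation; 6: 1–3 defects + rotation +
warp). Per synthesized image: patches are extracted from randomly
picked defective samples (pixels under the annotation mask, cropped to
the bounding box), rotated by a uniform angle in [0, 360)° (bilinear
for pixels, masks re-binarized at 0.5, bounding box expanded), and/or
elastically warped by a dense field interpolated (cubic) from uniform
±0.1·patch-size displacements on a 3×3 control grid — small
deformations, since warping adds interpolation artifacts and was found
upstream not to help. Placement draws uniform positions and accepts
only locations where *every* patch pixel lies inside the apple ROI
(rejection sampling, 50 attempts, then skip with a warning); pasting
is a hard overwrite of all channels under the mask, with no blending,
and overlapping defects are allowed (later pastes win). The ROI is the
largest connected component of pixels whose channel-mean intensity
exceeds 0.04 (≈10/255, separating the near-black background), holes
filled.

## Evaluation

Predictions are binarized at 0.5. Reported metrics per image: pixel
precision, recall, f-score, and the Class-Specific Recognition Error
`CSRE = (FN/(TP+FN) + FP/(TN+FP))/2` — the mean of the false-negative
and false-positive rates, i.e. one minus balanced accuracy — which
stays informative when defects are tiny relative to the apple. 0/0
terms are defined as 0. The overall table reports both the mean of
per-image metrics (primary) and pooled-count metrics; by default only
defective test images are scored (`include_healthy` opts the rest in —
whether healthy images participate upstream is unstated).

Per-class tables (4 macro classes, 10 sub-classes) score, for each
class, the images containing it, with ground-truth positives
restricted to that class's pixels and other-class defect pixels
excluded from the tallies (ignore label). This restricted+ignore
protocol is this package's declared convention; the published tables
do not state theirs.

## Phantom data

The phantom generator provides fully annotated synthetic data so the
entire pipeline is testable without the original (non-redistributable)
apple database. Each phantom is an ellipse (semi-axes ~34–44% of the
frame) with radial shading, band-correlated smooth texture (Gaussian
noise filtered at two scales, σ = 0.02) and per-band base reflectance
(NIR brightest), on a near-black background (level 0.02). Defects are
irregular blobs (thresholded Gaussian-filtered noise, largest
component, holes filled) stamped multiplicatively with class-dependent
contrast (0.30 for rot up to 0.62 for russet), softened 1 px at the
boundary; russet is additionally rendered at near-zero contrast in the
NIR band, emulating defects that are invisible in some spectral bands.
Masks are exact by construction.

What the phantom does **not** emulate: specular highlights, stem/calyx
confusers (the classic false-positive source on real apples), realistic
defect textures, shading gradients from directional lighting, and
inter-band misregistration. Passing the scaled-down learning-recovery
test therefore shows that the architecture, loss, synthesis and
protocol are implemented coherently and can fit a segmentation task of
the assumed structure — not that the reported real-data accuracy is
reproduced.

## Problem sizes used in tests

The learning-recovery experiment uses 96 train / 16 val / 32 test
phantoms at 128×128 with a reduced-width preset (`small_config`: stem
12, stages (12, 16), blocks (1, 2), t = 2, decoder (16, 12)) and at
most 30 epochs; the synthesis-ablation comparison trains setups 1 and
5 across three seeds with only 16 defective training images (the
regime where synthesis should matter). Protocol and oracle tests use
48×48 phantoms and closed-form fixtures.

## Known limitations

* CPU-only numpy engine: full-resolution multi-spectral training at
  the published scale is possible but slow; the engine is intended for
  correctness and desk-scale experiments.
* Single-fold protocol only (cross-validation was judged unnecessary
  upstream and is out of scope here).
* Binary head only; per-defect-type output heads are out of scope.
* Hard pasting performs no photometric harmonization; pasted defects
  keep their source illumination.
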