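# Methods

This note documents the models, losses and procedures the package
implements, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Problem setting

Detecting pests and diseases on eggplant fruit in field imagery is a
small-object detection problem with three characteristic lesion
morphologies: fruit-borer holes (near-circular cavities, often under
9×9 px at 640² input), fruit-rot lesions (irregular mid-size blobs) and
melon-thrips feeding stripes (elongated, strongly oriented), plus a
Healthy class for unlesioned fruit. Three properties drive the design:
targets are small (their IoU signal is noisy), oriented (isotropic
kernels wash out stripes), and weak-edged (downsampling smooths away the
discriminative high-frequency detail).

## Architecture

The baseline is the public nano-scale one-stage anchor-free detector: a
P1–P5 backbone of stride-2 CBS units (conv + batch norm + SiLU) and
C3k2 cross-stage blocks, closed by SPPF and a position-sensitive
softmax-attention stage; a top-down/bottom-up neck; and a decoupled
head with distribution-focal (DFL) box regression at strides 8/16/32.
Our NumPy implementation of this layout counts 2.5906 M parameters and
6.31 GFLOPs at 640² (conv-only FLOPs, 2 ops per multiply–accumulate, the
convention of the common profilers that produce published figures), in
agreement with the published budget of this model family.

Four independent switches define DFSNet:

* **PConv (P1–P2).** Four parallel branches pad the input asymmetrically
  on one side (amount k−1 = 2) and convolve with asymmetric kernels
  (1×3 for left/right, 3×1 for top/bottom) at the stage stride; outputs
  are concatenated and fused by a 2×2 CBS padded (0,1,0,1) so the fusion
  preserves size. The asymmetric-kernel parameter count stays below the
  3×3 convolution it replaces. Kernel length 3 and the fusion
  stride placement (stride in the branches, not the fusion) are our
  design choices.
* **C3k2-MSDA (backbone P3–P5).** A parallel path next to the standard
  C3k2 stage: a 1×1 reduction, then MSDA — 1×1 in-projection, channel
  split into a multi-scale stream F_m and an attention stream F_a;
  F_ms = F_m + WT₂(GELU(WT₁(F_m))) with WTConv wavelet convolutions;
  the DEE edge branch splits F_a into halves feeding horizontal and
  vertical depthwise gradient kernels (learnable, Sobel-initialised,
  replicate-padded so a constant map yields an exactly zero response),
  fuses them, gates through a sigmoid 1×1 and re-adds residually; the
  streams are concatenated, 1×1-projected and added to the block input.
  The two paths merge by concat + 1×1 fusion. The F_a1/F_a2 inputs of
  the two gradient kernels are the channel halves of F_a — the choice
  that keeps F_d = F_d1 + F_d2 shape-consistent. The DEE residual is applied at the
  F_a level (not the whole block input); the block-level residual
  already exists outside.
* **WTConv.** One orthonormal Haar step splits a map into LL/LH/HL/HH at
  half resolution (energy conserving; fixed, not learned). WTConv
  decomposes the LL chain `levels`-deep (default 2), applies an
  independent depthwise 3×3 to every subband at every level with
  per-channel gains, reconstructs by replacing each level's LL with the
  deeper reconstruction, and adds a base depthwise conv of the input.
  With identity kernels and a zero base path the operator is exactly the
  identity; it is linear (no norm/activation inside). Odd sizes are
  replicate-padded bottom/right and cropped after the inverse.
* **CSP-MSLA (neck).** The three neck fusion blocks feeding the head
  become cross-stage-partial MSLA units: 1×1 to the stage width, one
  channel half through MSLA plus a small depthwise conv, the other half
  identity, concat, 1×1 fuse. MSLA computes kernelised attention
  Y = φ(Q)·(φ(K)ᵀV) with φ = ReLU and an ε = 1e-6 normaliser guard, in
  K-first association order (O(N·d²) instead of O(N²·d)); multi-scale
  depthwise convolutions (3/5/7/9, summed with the identity) enhance the
  Q and K maps after their 1×1 projections, which is where positional
  information enters (the attention itself is permutation-equivariant).
  Heads default to 4.
* **SDDH (head).** A shared-tower head: per-level 1×1 projections into a
  common width (96), a weight-shared depthwise-separable tower (depth 4)
  with level-specific batch norms, and shared 1×1 predictors; box
  outputs are ltrb distances in grid cells through a softplus with a
  per-level learnable scale.

### The DFSNet budget

The reported compression target (1.8 M parameters, 5.4 GFLOPs at 640²)
is the only structural constraint available for the blocks above, so
the widths left unspecified were calibrated once against it:
CSP-MSLA stage widths (64, 96, 104) with a 96-wide top-down mid block
and depthwise-separable neck downsamplers, MSDA path widths (32, 32,
24), SDDH width 96 / depth 4. The resulting build measures 1.824 M and
5.42 GFLOPs. A head swap alone cannot account for the 0.79 M drop (the
baseline head holds only ~0.47 M parameters), so the budget is treated
as a joint constraint across the redesigned blocks.

## Scale-based dynamic loss

Box branch: L_SDB = β1·L_BS + β2·L_BL with L_BS = 1 − IoU + γ,
L_BL = d²(centres)/L² (L the enclosing-box diagonal, so L_BL ∈ [0,1) and
is translation invariant), β1 = 1 − δ + β3, β2 = 1 + δ − β3 (β1+β2 = 2
identically) and β3 = min(area(B_gt)/maxB_gt · θ · δ, δ). Defaults:
δ = 0.5, maxB_gt = 81 px² (the 9×9 infrared-small-target area bound; we
read "B_gt" as box *area*, the reading consistent with that bound),
γ = 0, θ = image size / feature size = the level stride.
In this orientation θ ≥ 8 saturates β3 at δ for any target larger than ~10 px²,
collapsing the weights to (1, 1); a config switch (`invert_theta`)
exposes the reciprocal reading. Small targets drive β2 → 1.5: centre
localisation dominates where IoU is unreliable.

Mask branch: L_SDM = β1′·L_MS + β2′·L_ML with L_MS = 1 − p·MIoU
(p = 1 by default) and L_ML = 1 − min(d̄)/max(d̄) + 4·Δθ̄²/π², where d̄ and
θ̄ are the mean radius and circular-mean angle of mask pixels about the
ground-truth box centre (a literal image-origin pole would make the
term translation-sensitive; the angle difference is wrapped to [−π, π]
and squared, the reading that keeps L_ML ∈ [0, 2] and matches the
4/π² template of aspect-consistency terms). The mask weights mirror the
box ones (β1′ = 1 + δ − β3 ∈ [1.0, 1.5), β2′ = 1 − δ + β3 ∈ (0.5, 1.0]),
which is our construction: it is the mirror of the box weights that
reproduces those stated ranges. β3 for masks uses the ground-truth pixel count as the area.
Degenerate cases: a single pixel at the pole has angle 0 by convention;
a vanishing circular resultant (perfect symmetry) likewise returns 0;
equal zero radii give a ratio term of 0.

Total objective: quality-weighted classification BCE over all anchors
(targets are the task-aligned soft scores; there is no separate
objectness output in an anchor-free head — an explicit objectness term is realised
as this quality weighting) plus λ · the score-weighted mean of L_SDB
over matches (λ = 7.5), plus the mean L_SDM when matched masks are
supplied. The baseline head keeps its DFL structure for parameter
parity, but training optimises L_SDB on decoded boxes for either head;
the DFL distribution term is out of scope.

## Assignment, metrics, inference

Assignment is task-aligned: candidates are anchors whose centre lies in
the ground-truth box, ranked by p_cls^0.5 · IoU^6, top-10 per ground
truth; anchors claimed twice keep the higher-IoU ground truth; target
scores are rescaled so each ground truth's best candidate carries its
best IoU. Ties resolve by stable sort order, so assignment is
deterministic. AP uses 101-point interpolation (the integral form of
the AP definition does not fix a discretisation; this is the COCO one);
mAP@50–95 averages IoU 0.50:0.05:0.95; reported P/R are per-class
values at each class's maximum-F1 point of the IoU-0.5 curve, averaged
over classes; classes absent from the ground truth are excluded from
means; no detections ⇒ P = 0 by convention. NMS is greedy per class
(IoU 0.7, confidence 0.25 by default, both exposed).

Training uses AdamW (lr 0.001, β1 0.9, weight decay 5e-4 on conv
weights only), batch 16, constant schedule — the reference training configuration.
The numerical stack is a self-contained reverse-mode autograd over
NumPy (im2col convolutions, kernel-loop depthwise path); gradients of
every primitive are finite-difference tested.

## Synthetic scenes

The field dataset is not redistributable, so a parametric generator is
the canonical input: textured green background, one or two shaded
dark-purple fruit ellipses with a specular streak, and lesions drawn
with class-specific geometry — borer holes 4–14 px diameter (mostly
under the 81 px² cap, so they exercise the β3 regime), rot blobs
15–60 px via randomised star polygons, thrips stripes 30–120 px long
with stripe aspect ≥ 6 and a slight wiggle (emitted only if the clipped
stripe's box keeps height/width ≥ 4). Lesions are clipped to the fruit
mask, so every lesion box centre lies inside its fruit; a fruit is kept
lesion-free with probability 0.25 and then contributes one Healthy box.
Boxes are tight over the drawn pixels; instance pixel sets are emitted
on request for the mask branch. Everything is deterministic given the
generator seed.

What the generator does *not* emulate: real illumination variation,
occlusion by leaves, camera noise statistics, background clutter
resembling lesions, or label noise. Passing the synthetic benchmark
therefore demonstrates that the pipeline — rendering, I/O,
augmentation, assignment, loss, optimisation, decoding, evaluation — is
correct and can fit coherent lesion geometry; it says nothing about
accuracy on real field imagery.

## The reduced-scale smoke benchmark

`dfsnet.train.smoke_train_config` fixes the benchmark: a tiny-width
DFSNet (width 0.125, input 128², ~0.21 M parameters) trained on 64 easy
synthetic scenes (one large fruit, at most one large lesion of each
class) for 80 epochs at batch 8. The learning rate is 0.005 rather than
the full-scale 0.001 because the run sees only ~640 optimiser steps;
at 0.001 the model barely leaves initialisation. With the fixed test
seeds the run halves its training loss within 10 epochs and reaches a
best validation mAP@50 of ~0.76 (evaluated every 10 epochs at
confidence 0.1); the problem sizes were chosen so the whole run takes
minutes on a single CPU.

## Split protocol

Partition sizes are floor(n·ratio) per split with every remainder item
assigned to the training split. At 7:2:1 this maps 7,256 items to
(5,080, 1,451, 725); plain floor gives 5,079 for train and
largest-remainder rounding also disagrees, so the remainder-to-train
rule is the one consistent with those counts. The shuffle preceding
allocation is seeded.

## Known limitations

* Forward/backward run on one CPU via BLAS; full-scale 640² training is
  out of reach at reasonable time — the package trains reduced-scale
  models and *profiles* full-scale ones.
* The smoke benchmark is stochastic across seeds; its mAP margin over
  0.6 (≈0.76 under the fixed test seeds) has not been characterised as
  a distribution.
* The mask branch is exercised at the loss level (matched pixel sets);
  no mask prediction head is assembled.
* β3 saturation under the default θ orientation means the dynamic
  weighting is mostly inactive at full scale unless `invert_theta` is
  set; we implement the stated form and expose the switch.
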