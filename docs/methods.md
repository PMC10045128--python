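# Methods

This note records the modeling and numerical choices behind `ratunet`: what
the network computes, what the synthetic phantoms do and do not emulate, and
the decisions taken where the design was genuinely open.

## Network

The segmentation network is a U-shaped encoder–decoder over single-channel
N×N slices (N a multiple of 32) at a constant channel width C.

**Encoder.** An initial 3×3 convolution lifts the input to C channels. Level
0 then applies two blocks — each block is batch normalization → ReLU → 3×3
same-padding convolution — and adds the block chain's output to the
preserved initial-conv output (a pre-activation residual connection). Levels
1–4 each begin with 2×2/stride-2 max pooling whose per-window argmax indices
are recorded; level 1 applies two blocks, levels 2–4 three blocks, each
level ending in a residual addition of the pooling output. A fifth pooling
reaches N/32. The encoder block counts (2, 2, 3, 3, 3) are the unique
assignment consistent with a 14-convolution encoder that starts with two
equivalent block processes at the first pooled level.

**Decoder.** Each of the four inner levels starts with max unpooling driven
by the paired pooling's stored indices — the deepest pooling feeds the first
unpooling, and so on outward — scattering features back to their original
spatial positions with zero fill elsewhere. The unpooled map is concatenated
(decoder features first) with the corresponding encoder addition output into
2C channels, reduced to C by one block, refined by three blocks, and closed
with a residual addition of the reducing block's output. The final level
unpools to N×N, concatenates with the level-0 encoder output, and applies a
reducing block, a sigmoid-activated block, and a 1×1 convolution that
consolidates the C channels into one. The decoder therefore holds 19
convolutions (4 levels × 4, plus 2 blocks and the 1×1 head), and the last
level carries no residual addition — the only configuration consistent with
the 19-convolution decoder inventory. A sigmoid on the 1×1 output maps the
single channel to [0,1]; a linear 1×1 layer after the sigmoid block alone
would not bound the output, and every downstream contract (thresholding,
Dice loss) needs probabilities.

**Inventory.** 33 convolutions (14 + 19), 5 poolings, 5 unpoolings, for any
valid N and width. `NetworkSpec` is always derived by traversing the
instantiated graph, never hard-coded.

**Engine.** The graph runs on a small NumPy engine written for this package:
im2col matrix-multiply convolutions, batch normalization with running
statistics, index-recording pooling, and hand-routed reverse-mode gradients
(residual additions sum gradients; concatenations split them). The full
backward pass is validated against central finite differences in double
precision in the test suite. Adam uses β₁ = 0.9, β₂ = 0.999, ε = 1e-8;
convolutions use He initialization; batch norm uses momentum 0.1 and
ε = 1e-5; pooling ties break to the first maximum in row-major window
order. All of this is deterministic given the seeds.

A note on the unpooling identity: `pool(unpool(pool(x))) == pool(x)` holds
exactly for non-negative feature maps. If a window maximum is negative, the
zero fill introduced by unpooling wins the re-pool, so the property is
asserted on non-negative inputs only.

## Preprocessing

Intensities are standardized with the dataset-level z-score
(I − μ)/σ, where μ and σ are the population mean and standard deviation
pooled over **every voxel of every training volume**, background included;
the statistics are frozen after training-set computation and reused for
validation, test, and inference, and are kept separately per modality since
DWI and T2WI networks are trained independently. The divide-by-n population
convention is fixed because at dataset voxel counts the n−1 correction is
negligible but a convention must be chosen. Normalization is computed in
float64 so that re-pooling the normalized training set returns mean 0 and
standard deviation 1 to better than 1e-9.

## Augmentation

Training slices are augmented on the fly with one affine transform per draw:
shear (uniform within ±0.3 rad, realized as a horizontal shear by tan θ),
rotation (±30°), isotropic zoom (scale factor in [0.8, 1.2] about the image
center, zero-padded), composed in the fixed order shear → rotate → zoom,
followed by a horizontal flip with probability 1/2. Images are interpolated
bilinearly, masks by nearest neighbor, so masks stay binary; identity
parameters are an exact no-op and a pure flip is an exact axis reversal.
Augmentation never touches validation or test data. The nominal protocol of
a 1000-fold expansion across a 100-epoch run is realized as 10 fresh
variants per original slice per epoch (`per_epoch_factor = 10`); desk-scale
runs in the tests and examples use factor 1, which keeps the stream
mechanics identical at a smaller problem size.

## Training protocol

Soft Dice loss Λ = 1 − (2Σpg + ε)/(Σp + Σg + ε) with ε = 1e-6, computed
jointly over all pixels of a mini-batch (batch-global Dice, the most common
reading when per-image averaging is unspecified); ε defines the both-empty
limit (loss 0). Adam starts at 5e-4; after epoch 20 the rate decays linearly
to 1e-4 at the final epoch (a step schedule is available behind
`lr_schedule: step` since "gradually decreased" admits both readings).
Batches of 8, 100 epochs at full fidelity. The checkpoint with the best
validation Dice is returned; training curves record soft loss and binarized
Dice from the training batches plus a clean inference pass over validation
(Dice and pixel accuracy both, since "accuracy" alone is ambiguous). All
randomness — splits, folds, initialization, augmentation, shuffling — flows
from explicit integer seeds.

Subjects are partitioned 6:2:2 (largest-remainder rounding) and five-fold
cross-validated strictly at the subject level: slices of one animal never
appear on both sides of any partition, and the tests assert this.

## Evaluation

Overlap metrics come from voxelwise confusion counts: Dice
2TP/(2TP+FN+FP) (defined as 1.0 when both masks are empty; distance metrics
and sensitivity instead raise errors on empty inputs, because silent
conventions hide upstream failures), sensitivity TP/(TP+FN), and
sensibility 1 − FP/(TP+FN), which is deliberately left unclamped — heavy
over-segmentation legitimately drives it negative.

Contours are per-slice 2-D boundaries (a foreground voxel with at least one
in-plane 4-neighbor outside the mask or image), unioned into a 3-D point set
of voxel centers at index × spacing in mm. The Hausdorff distance is the
symmetric max-min over the two point sets; the average Hausdorff distance is
the symmetric mean of the two directed average nearest-neighbor distances —
the most common reading of "average distance instead of the maximum", and
symmetric like the max form. Distances are 3-D Euclidean in physical space,
so anisotropic voxels (1 mm slices vs 0.1–0.2 mm in-plane) are handled
correctly; whether a per-slice 2-D average was intended instead is not
determinable, and the 3-D reading is the implemented choice. Nearest
neighbors use a KD-tree; the tests verify exact agreement with a full
pairwise-distance oracle. The paired t-test is the classical one on
per-subject score differences (two-tailed p, significance at 0.05), with an
explicit error on zero-variance differences.

Binarization threshold is 0.5 (≥ convention at the boundary); an optional
largest-connected-component cleanup exists but is off by default.

## Phantom generator

The generator emulates the *structure* of coronal stroke-rat acquisitions,
not MR physics: 15 slices, 2.56 cm field of view, matrix 128 (DWI-like,
0.2 mm pixels) or 256 (T2WI-like, 0.1 mm); smaller matrices (e.g. 64) are
accepted for desk-scale runs. Per slice: an elliptical brain (default
semi-axes 7.5 × 5.5 mm at mid-volume, scaled by 0.55 + 0.45·sin(π(z+½)/n)
toward the ends, giving a mid-slice foreground fraction near 0.20), a dark
skull-gap ring (intensity 0.15 vs brain 1.0), and a scalp ring at 0.7 —
deliberately brain-like so plain thresholding fails and the segmentation
task is non-degenerate. A hyperintense lesion disk (gain 1.3–1.8×,
DWI-bright ischemia surrogate; the same mechanism is reused for T2WI-like
cohorts) occupies one hemisphere on a contiguous slice range and is
validated to lie inside the brain ellipse. The clean image is blurred
(σ = 0.6 px, a partial-volume surrogate), multiplied by a bias field
exp(p(x, y)) with p a second-order polynomial capped at amplitude 0.3
(radiofrequency-inhomogeneity surrogate), and degraded with Rician noise —
the magnitude of signal plus complex Gaussian — at σ defaulting to 1/15 of
brain intensity (SNR ≈ 15). The ground-truth mask is the exact ellipse
interior, lesion included, rings excluded.

Cohorts randomize geometry, lesion, bias, and noise within fixed ranges from
per-subject seeds derived from one master seed. What passing tests show is
that the pipeline learns and evaluates correctly on images with this
structure; the phantoms do not reproduce rat neuroanatomy, susceptibility
artifacts, k-space effects, or inter-scanner variation, so metric values on
phantoms say nothing quantitative about scanner data.

## Problem sizes

Full fidelity (width 64, N = 128/256, 100 epochs, 55 subjects) is supported
but the shipped tests and examples run the same code desk-scale: width 16 at
N = 64 for the end-to-end learning check (40 training and 10 held-out
subjects, 10 epochs, batch 8, augmentation factor 1), width 4–8 for
structural and smoke tests. The end-to-end check requires held-out mean
Dice ≥ 0.90 and mean average Hausdorff ≤ 1.0 mm; the representative run in
the README reaches Dice ≈ 0.98 at ≈ 0.1 mm on held-out phantoms.

## Known limitations

* No bias-field correction, registration, or resampling — inputs are
  consumed as acquired, by design.
* The engine is CPU-only NumPy; full-fidelity 100-epoch training is
  possible but slow compared to GPU frameworks.
* Multimodal fusion, 3-D convolutions, competitor architectures, and
  morphological post-processing pipelines are out of scope.
* Sensibility is unbounded below; cohort summaries can be dominated by a
  single grossly over-segmented subject.
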