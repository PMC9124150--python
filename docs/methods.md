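# Methods

## Problem and scope

`camseg` segments lung tumors in thoracic CT. A scan is a 3D grid of
Hounsfield-unit (HU) intensities; the target is a binary voxel mask of
tumor tissue. The package implements the complete workflow — CT
preprocessing, three volumetric encoder-decoder networks (U-Net, V-Net and
the channel-attention network SegChaNet), compound dice losses, an
Adam-with-plateau training protocol including k-fold majority-vote
ensembling and grad-CAM saliency, and a volumetric evaluation suite — plus
a seeded thorax-phantom simulator so every stage runs end to end with known
ground truth and no external data.

## Preprocessing

Applied in fixed order per scan:

1. **HU truncation** to [−1000, 400] HU. Air is ≈ −1000 HU and values above
   400 HU carry no information for lung anatomy; clipping is idempotent.
2. **Z-normalization** to zero mean, unit variance, computed *after*
   clipping with the population standard deviation (the sample/population
   distinction is immaterial at volume scale but is fixed so results are
   bit-reproducible). Constant volumes are rejected as degenerate.
3. **Resampling** to a cubic grid (default 128³; the desk-scale study
   conditions below use 32³), linear interpolation for images, nearest
   neighbour for masks so no labels are invented. Spacing is rescaled by
   the shape ratio, preserving physical extent.

Training-time augmentation draws from one seed: an optional left-right
flip applied to image and mask alike, an optional intensity inversion
v → −v (image only; on a z-scored volume it preserves zero mean and unit
variance — this is the interpretation adopted for "white-to-black
inversion", for which no formula is published), and an in-plane axial
rotation with angle uniform in ±10°. Rotated volumes are padded with the
volume minimum, which after clip + z-score is the air value; masks use
nearest-neighbour rotation with zero padding.

## Channel attention module (CAM)

The fusion block at the heart of SegChaNet combines a low-level encoder
map X_L (fine detail, c_L channels) with a high-level decoder map X_H
(coarse semantics, c_H channels at half resolution or less):

    X_L′  = conv3(X_L)                   3×3(×3) conv, c_L → c_H channels
    g     = GAP(X_H)                     per-channel global average pool
    X_gL  = conv1(X_L′) ⊙ g              1×1(×1) conv, then channel k scaled by g[k]
    X_cam = X_gL + up(X_H)               bi/tri-linear upsampling to X_L's grid

Design points that the source description leaves open, fixed here:

- The per-channel gating is read as `conv1(X_L′)[k] · g[k]` for
  k = 0…c−1 (the printed formula is garbled); this matches the prose
  "multiplying the low-level features by the high-level features using a
  1×1 convolution process".
- No squashing nonlinearity is applied to the pooled gate vector, because
  none appears in the defining equations; `gate_activation="sigmoid"` is
  available as a config switch.
- "Global pooling" is average pooling; max pooling is never mentioned.
- conv3 maps c_L → c_H and conv1 maps c_H → c_H so the additive fusion
  type-checks; channel counts are not published.
- Bilinear upsampling generalizes to trilinear for 3D maps, align-corners
  convention.

The functional form (`camseg.cam`) is numpy-only and is cross-checked in
the tests against a literal per-index loop implementation; the trainable
`CAMBlock` shares the same arithmetic inside the network graph, and a test
asserts the two agree.

## Architectures

All convolutions are same-padded so skip connections and the CAM fusion
need no cropping; a crop-based "unpadded" variant is deliberately out of
scope because the fixed cubic grid and the symmetric decoder require shape
preservation. All three networks map (C, D, H, W) → per-voxel
probabilities at the input resolution.

- **U-Net**: depth levels of (conv 3³ + ReLU)×2, 2× max pooling between
  levels, channel count doubling per level, nearest-neighbour upsampling
  with skip *concatenation* on the way up, 1×1×1 conv + sigmoid head.
- **V-Net** (3D only): a stem conv, then residual stages x + F(x) with
  F = conv-BN-ReLU-conv; downsampling by stride-2 2×2×2 convolutions that
  double the channels (no pooling); decoder mirrors with nearest
  upsampling, channel-halving convs and *additive* skips; 1×1×1 conv +
  softmax head (≥2 classes). Zeroing a stage's branch weights makes the
  stage the identity — asserted in tests.
- **SegChaNet**: depth (default 4) encoder blocks of
  (conv 3³ + BatchNorm + leaky ReLU)×2 with 3D max-pool downsampling; at
  the bottleneck a sequential dilated-conv stack whose dilation doubles
  layer by layer (default schedule 1, 2, 4) to enlarge the receptive field
  without further downsampling — the stack's receptive field
  1 + 2·Σd must fit inside the deepest feature map or the forward pass
  refuses; decoders upsample 2× and fuse each encoder skip through a CAM
  block (concatenation fallback when `use_cam=False`, and per-level control
  via `cam_levels` since the source is ambiguous about whether every skip
  carries CAM); optional deep supervision upsamples every decoder output to
  full resolution and concatenates before the head; sigmoid head.

**Head bias prior.** Tumor voxels are a fraction of a percent of a scan.
Sigmoid heads are therefore initialized with a negative bias
(`head_bias_init = −6`, foreground prior ≈ 0.25%) so optimisation starts
near the class prevalence instead of at p = 0.5 everywhere — the standard
initialization for extremely imbalanced dense prediction. Without it the
first few hundred steps are spent uniformly suppressing background.

**Batch normalization semantics.** Cases are processed one at a time and
minibatches are formed by gradient accumulation, so normalization
statistics are per-sample over spatial locations; exponential running
averages (momentum 0.1) are used at inference. Inference is deterministic.

## Numerical core

No deep-learning framework is used: the networks run on a compact
reverse-mode autodiff engine (`camseg.nn`) over numpy arrays, with
convolutions evaluated as one BLAS product per kernel tap on flat offset
views of the zero-padded array (stride-1 case) or via an explicit im2col
matrix (strided case). Every op is validated against central finite
differences in the test suite. Feature tensors are float32; losses and
metrics compute in float64.

## Losses

With binary target y and prediction ŷ ∈ [0,1], set sizes are relaxed to
sums: |A∩B| → Σyŷ, |A| → Σy, |B| → Σŷ, smoothed by ε in numerator and
denominator.

- **Overlap loss (`eq1`)**: 2 − (IOU + DSC), range [0, 2]; 0 at perfect
  nonempty overlap, 2 for disjoint nonempty masks. The printed form
  "2 − IOU + DSC" increases with better overlap and cannot be a loss, so
  the parenthesised reading is implemented. Default ε = 10⁻⁷ (near-exact
  set overlap); pass ε = 1 for smoother gradients when training with it.
- **Dice + BCE (`eq6`)**: (1 − soft DSC with ε = 1) plus mean binary
  cross-entropy with ŷ clamped to [10⁻⁷, 1−10⁻⁷]. This is the default
  training loss; both are selectable per run because the source is
  ambiguous about which produced its headline model.

## Training protocol

Adam (β = 0.9/0.999), initial learning rate 5·10⁻⁴ by default with the
published search grid {1e-4, 1e-3, 3e-3} × minibatch {2, 4, 8, 12}
available through `run_hyperparameter_grid`. The monitored quantity is
validation binary cross-entropy; after 15 epochs without improvement the
rate is multiplied by 0.1 (patience and factor both configurable; cooldown
zero — the simplest reading of the published schedule sentence, which
conflates "after 15 epochs" with "0.1 per ten epochs"). Early stopping is
not implemented (never stated). All randomness — initialization, shuffling,
augmentation — flows from one seed; two runs with the same seed produce
identical histories. `ensemble_majority_vote` implements the per-voxel
majority over an odd number of fold predictions; `kfold_split` partitions
cases so each appears in exactly one validation fold.

Grad-CAM pools the gradient of the summed foreground probability over each
channel of a chosen layer (spatial mean), forms ReLU(Σ w_k·act_k),
upsamples to input resolution and max-normalises to 1; the technique is
named in the source without parameters, so this is the textbook variant.

## Phantom simulator

Each case is a geometric thorax on an air background (−1000 HU): a body
ellipsoid (40 ± 20 HU), two lung ellipsoids (−800 ± 50 HU), a tubular
trachea branching into two bronchi at air HU, and 1–3 spherical nodules
(soft-tissue intensity 30 ± 15 HU) placed strictly inside lung tissue via a
distance transform, with diameters drawn from the published 5–32 mm
clinical size range; additive Gaussian noise (σ = 20 HU) is applied last.
A union-of-spheres "lobulated" option mimics heterogeneous nodules.
Everything derives from one seed.

What the phantoms *do not* model: CT physics (beam hardening,
reconstruction kernels, partial-volume blur), anatomical variability,
vasculature, and pleural or juxta-vascular nodule attachment — the
hardest real-world cases. Passing the training and evaluation checks on
phantoms therefore demonstrates that the machinery (gradients, losses,
attention fusion, metrics, protocol) is correct, not that the trained
weights transfer to patient CT.

## Desk-scale study conditions

Training-based checks run at a reduced scale chosen once: phantoms of
32³ voxels at 3 mm spacing (≈10 cm field of view) with nodule diameters
9–21 mm (inside the clinical 5–32 mm range, ≥3 voxels across at this
grid), and a reduced SegChaNet of depth 3, base 8 channels, dilation
schedule (1, 2) — the deepest 8³ map cannot host the full (1, 2, 4) stack,
whose 15-voxel receptive field the forward pass rejects. Two standard
experiments are wired into the tests and the acceptance script:

- **Overfit**: one phantom, 300 Adam steps at lr 10⁻³, dice+BCE loss;
  soft-DSC on the training case must reach ≥ 0.95.
- **Generalization**: 16 training phantoms, 4 held-out; identical training
  for `use_cam=True` and `use_cam=False`; mean hard DSC of the CAM variant
  must reach ≥ 0.80, and both scores are reported side by side. At this
  toy scale the direction of the CAM gain is recorded, not asserted.

## Degenerate-case conventions (metrics)

Both masks empty → DSC = IOU = NSD = 1 and sensitivity = 1 (perfect
agreement); exactly one empty → DSC = IOU = 0 and the Hausdorff distance
is undefined (NaN or error, per `on_empty`). A foreground voxel is a
surface voxel iff any 6-neighbour is background; distances are between
voxel centres in physical mm. JI is treated as identical to IOU; published
tables in which "JI" exceeds DSC are impossible under the standard
definitions and are not used as oracles. Binarization uses strict
`prob > threshold`, so a tie maps to background. "Accuracy" is voxel
accuracy (TP+TN)/total.

## Known limitations

- Single-sample batch-norm statistics differ from true minibatch
  statistics; at desk scale this is benign but large-batch behaviour is
  not reproduced.
- The tracheal/bronchial auxiliary segmentation task mentioned alongside
  the preprocessing has no published labels, loss or weighting and is
  excluded; the phantoms still draw airways so the HU histogram is
  realistic.
- DICOM series assembly is out of scope; volumes enter as NIfTI/MetaImage.
- Published patient-CT benchmark figures for this model family require a
  large external archive and GPU-scale 128³ training; they are not
  reproduced here.
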