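# Methods

## Model

The segmentation network is a three-resolution encoder/decoder with a
transformer bottleneck and a self-supervised landmark branch.

**Encoder.**  Two downsampling steps (2×2 max-pool) separate three groups
of two 3×3 conv + instance-norm + ReLU layers, giving feature maps at H×W,
H/2×W/2 and H/4×W/4 with channel widths C1 < C2 < C3 (default 64/128/256).
The depth is deliberately shallow: thin vessels are only a few pixels wide
and disappear under aggressive downsampling.  Instance normalisation is
used because the batch size is one image; without it, the auxiliary
landmark objectives pulling on the shared encoder drift the feature scales
and segmentation stalls for many epochs.

**Transformer bottleneck.**  The H/4 features are split into p×p patches
(default p = 8), each linearly embedded (a p×p stride-p convolution) and
summed with a learned position embedding; `N_t` (default 4) pre-norm
layers apply multi-head self-attention and an MLP, each behind a residual
(`Z' = MHSA(LN(Z)) + Z`; `Z = MLP(LN(Z')) + Z'`); a linear patch-merging
layer restores the H/4×W/4×C3 map.  Two nonstandard choices:

* Position embeddings live on a fixed base grid and are bilinearly
  resized to the actual token grid, so one parameter set serves any input
  size whose H/4, W/4 are divisible by the patch size.
* The patch-merging projection is zero-initialised.  A conv bottleneck is
  locality-preserving from initialisation, but a randomly initialised
  attention stack feeds the decoder unstructured token mixtures; fading
  the bottleneck output in (ReZero-style) lets the decoder first learn
  from the skip connections and markedly accelerates early training.

**Landmark detector.**  A 1×1 convolution projects the H/4 features to K
response channels (default K = 32).  Each channel is normalised by a
softmax over all spatial sites and read out by soft-argmax — the
probability-weighted mean of site coordinates — giving K continuous
(row, col) landmarks in feature-grid units.  The projection is initialised
with a large gain (20× the usual He scale): with a standard init every
response map is nearly uniform, soft-argmax collapses all landmarks onto
the grid centre, and the self-supervised losses sit at a symmetric
stationary point they cannot leave.  Peaked initial maps break that
symmetry; training then refines the positions.

**Decoder.**  Stage one consumes the bottleneck output concatenated with K
Gaussian heatmaps (σ = 0.7 grid units) rendered at the predicted
landmarks; stage two consumes the upsampled (bilinear) stage-one output,
the H/2 encoder skip, and additionally a max-pooled copy of the
full-resolution encoder features — this third input restores local texture
that global attention tends to smooth away; stage three consumes the
upsampled result with the H/W skip and ends in a 1×1 conv + sigmoid.
Variants: `unet` swaps the transformer for two conv blocks and uses a zero
Gaussian map, `transunet` keeps the transformer but no landmarks,
`transunet_sld` enables everything, so ablations are pure module swaps.

The Gaussian-map definition admits two readings — K spatial heatmaps, or a
K-vector of scalars measuring predicted/pseudo-label landmark agreement.
The decoder needs a spatial input, so the heatmap reading centred at the
*predicted* landmarks is the default (it is also the only reading
available at inference, when no ground truth exists); the scalar reading
is kept as `scalar_gaussian_map`.

## Objective

`L_total = λ1·L_seg + λ2·L_adv + λ3·(L_ctr + L_cst) + λ4·L_lmd`,
λ = (0.2, 0.3, 0.4, 0.1).

* `L_seg` — mean binary cross-entropy plus `1 − Dice`
  (`Dice = (2Σpy + ε)/(Σp + Σy + ε)`, ε = 1e−6), the per-pixel term.
* `L_adv` — a global shape term.  A small critic (four stride-2 convs,
  LeakyReLU, global average pool, sigmoid) sees the segmentation map
  alone; it minimises `−[log D(Y) + log(1 − D(Ŷ))]` on detached
  predictions while the generator minimises the non-saturating
  `−log D(Ŷ)`.  The minimax generator form saturates when the critic
  wins early, so the non-saturating form is used.  The critic runs at
  lr/10 and updates every second generator step; at equal rates it
  overpowers the generator on small synthetic runs (binary masks vs.
  smooth maps are trivially separable) and segmentation collapses.
* `L_cst` — equivariance: landmarks of an affine-warped view, pulled back
  through the inverse affine (translation rescaled to feature-grid
  units), must match the original landmarks (mean squared distance).
* `L_ctr` — NT-Xent (temperature 0.2) over per-landmark descriptors of
  the original and a photometrically jittered view: positives share the
  landmark index, all other landmarks in either view are negatives.
  Descriptors are L2-normalised bilinear samples of the deep encoder
  features at the landmark coordinates (coordinates detached, so the
  gradient shapes the features); the K-dimensional head responses proved
  too low-dimensional to carry a useful contrastive signal.
* `L_lmd` — mean squared distance between image landmarks and
  pseudo-label landmarks extracted from the ground-truth mask through
  the *shared* encoder.  The pseudo-labels are treated as stop-gradient
  targets; letting gradients flow through both arms admits the trivial
  solution of collapsing both to a constant.

Optimisation is Adam (β = 0.9/0.999), lr 0.001, weight decay 0.0005, one
image per iteration, no schedule.  Loss weights that are exactly zero skip
their entire branch and consume no randomness, so a run with only the
segmentation weight is bit-identical to plain Dice+BCE training (verified
in the suite).

## Data pipeline

Readers understand the DRIVE / CHASE-DB1 / STARE on-disk layouts (masks
binarised at 50% of maximum; DRIVE uses the first annotator; the stated
DRIVE protocol trains on the last twenty images, and a `swap_split` flag
restores the common convention).  Foreground-maximising slicing places a
window of 0.6× the image height/width on a 3×3 positional grid — offsets
{0, ½, 1} of the slack per axis, the reading under which exactly nine
slices exist — and keeps the slice with the highest vessel fraction,
row-major on ties.  Augmentation: seeded flips, 90° rotations plus ±15°
small-angle rotations, scaling in [0.8, 1.2] (masks resampled nearest),
and photometric contrast/brightness jitter on the image only.  Training
images are plainly resized (512×512 default; 256×256 supported for the
resolution study).

## Synthetic data generator

The generator emulates the properties the method depends on: a branching
vascular tree (recursive midpoint-displaced polylines; per-level width
`root_width · width_decay^level`; a `thin_fraction` of terminal branches
drawn at 1 px), rendered darker than a vignetted background by exactly
`0.4 · contrast` gray levels inside a circular field of view of radius
0.48·min(H, W), with seeded Gaussian pixel noise.  Defaults (contrast 0.6,
noise σ 0.02, two root vessels, ~10% vessel pixels) give a low-contrast
but learnable task.  It does *not* emulate the optic disc, macula,
pathology, inter-image illumination fields or annotation noise, so passing
results demonstrate that the pipeline learns and that its components
interact as designed — not clinical-grade accuracy on real fundus images.

The photometric "style" view is parametric jitter (per-channel gamma
0.7–1.4, contrast scale 0.8–1.25 about mid-gray, brightness ±0.15, ±0.1
channel mixing), purely per-pixel so it commutes with cropping; the affine
view samples rotation/scale/shear/translation within configurable bounds
about the image centre, with bilinear resampling for images and nearest
for masks.

## Evaluation

Pixel confusion counts (optionally restricted to the field of view) give
accuracy, sensitivity, specificity and F1; a metric with an empty
denominator is reported as NaN and flagged, never as 0.  Both pixel-pooled
(default headline) and per-image-mean aggregation are reported, since the
pooling convention differs across the literature.  Predictions are made at
the training resolution and resized back (nearest) to the native mask
before counting.  Leave-one-out orchestration trains N folds with
per-fold seeds `seed + fold` and averages fold metrics.  Error overlays
follow the standard colour code: white TP, blue FN (missed vessels), red
FP, dimmed image elsewhere.

One documented quirk: prose definitions of FP/FN sometimes swap the two
relative to the TP/TN definitions; this implementation uses the standard
orientation (FN = vessel pixel predicted background), consistent with the
blue-FN/red-FP overlay convention.

## Scaled-down study sizes

Tests and the acceptance script exercise a reduced profile chosen as the
package's small-scale configuration: 64×64 images, channels (16, 32, 64),
K = 32 landmarks, two transformer layers with 4 heads and patch size 4,
16 training pairs, 8 held-out pairs, 30 epochs.  Under this budget the
landmark-guided variant reaches held-out F1 ≈ 0.95–0.99 and exceeds the
plain U-Net baseline trained identically, echoing the ablation direction;
the numbers are produced by the test suite and `scripts/acceptance.py`,
not asserted from elsewhere.

## Numerical notes

* All tensors are float32; the Gaussian heatmap front-end computes in
  float64 so far-field values remain strictly positive.
* BCE and adversarial logs clamp probabilities to [1e−7, 1 − 1e−7].
* The NT-Xent loss uses a detached-max log-sum-exp; masked self-pairs get
  a −1e9 logit.
* Soft-argmax coordinates are convex combinations of site coordinates and
  therefore always inside the grid; ties in max-pooling resolve to the
  first maximal element.
* The autodiff engine is validated against central finite differences for
  every primitive the model uses.

## Known limitations

* No GPU path; practical problem sizes are small images on CPU.
* The contrastive objective assumes the landmark ordering is consistent
  across views of the same image (shared detector), not across subjects;
  there is no cross-image correspondence.
* The adversarial term's balance heuristics (critic lr/update ratio) were
  chosen for small synthetic runs; large-scale training may need different
  ratios.
* The pseudo-label loss compares landmarks index-wise by default; an
  entropy-regularised optimal-transport variant
  (`landmark_matching="sinkhorn"`) is available but has not been tuned at
  scale.
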