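# Methods

This note documents the models, procedures, parameters and numerical choices
behind `emseg`.  It is written for users who want to know what the toolkit
computes and what its tests do and do not demonstrate.

## Scope and data model

`emseg` is a headless, scriptable toolkit for CNN-based segmentation of
volumetric electron-microscopy (EM) image stacks: slice-wise 2-D semantic
segmentation, flood-filling 3-D instance segmentation, classic preprocessing
filters, postprocessing into labeled 3-D objects, quantitative evaluation,
and mesh/annotation export.  All volumes are `(z, y, x)` arrays with physical
spacing `(sz, sy, sx)` in nanometres.  The default spacing (30, 6, 6) nm
corresponds to serial-section SEM at 6 nm per pixel in-plane and 30 nm
section thickness; it is configurable everywhere, since acquisition
resolutions vary (isotropic FIB-SEM data would use, e.g., (3, 3, 3) nm).
Label volumes use nonnegative integer ids with 0 as background; RGB-encoded
label images pack the id little-endian as `id = R + 256·G + 65536·B`.

## Classic filters

The filter catalog (`gaussian`, `median`, `clahe`, `invert`, `threshold`)
covers the preprocessing an EM pipeline typically applies before CNN
inference.  Chains are applied strictly left-to-right and are bit-identical
to applying each filter separately; filters run slice-wise unless a spec
requests a true volumetric (3-D) kernel.

CLAHE is implemented natively with an explicit contract.  The image is tiled
(default block size 127 px), each tile's 256-bin histogram is clipped at
`max_slope / bins` of the tile mass (default max slope 1.50 — the slope bound
of the tile's transfer function), the clipped excess is redistributed
uniformly, and per-tile equalization look-up tables are bilinearly
interpolated between tile centres (Zuiderveld's scheme).  A tile whose
histogram has a single occupied bin maps through the identity — a flat region
carries no contrast to redistribute — which makes a constant slice an exact
fixed point.  Other tools define the "max slope" → clip-limit conversion in
slightly different ways; ours is the one stated above, tested against a
direct per-tile equalization oracle in the unlimited-slope limit, and no
claim is made that it matches any particular GUI implementation bit for bit.

## The NumPy network engine

No deep-learning framework is used: `emseg.nnet` is a minimal CPU engine
(float32 NumPy) providing 2-D/3-D same-size convolutions via im2col matrix
multiplication with explicit backpropagation, ReLU, 2×2 max-pooling,
nearest-neighbour upsampling, residual/highway/dense composition, and Adam.
The networks in scope are small (stride-1 stacks of ≤16 3×3 convolutions, a
4-level U-Net, a 3-D FFN over a ≤17³ field of view), so CPU matmul is
adequate at the problem sizes below.  All initialisation flows from a single
`numpy.random.Generator`; training is bit-reproducible for a fixed seed and
BLAS.

Convolutions use zero padding ("same" shape).  Two initialisation choices
matter and were adopted after observing optimisation failure modes, both
standard practice:

* residual branches are He-initialised and scaled by `1/sqrt(n_layers)`;
  without this a 9-layer stride-1 residual stack emits logits of order ±200
  at initialisation and the sigmoid saturates irrecoverably;
* the 1×1 head convolution is zero-initialised, and `train2d` sets its bias
  to the training-set foreground-prior logit.  With rare foreground (a few
  percent of pixels, typical for organelles) the square loss — whose
  gradient carries a `p(1−p)` factor — otherwise collapses to the
  all-background constant under Adam and cannot escape.

## 2-D CNN segmentation

Four topologies are available: `unet` (contracting/expansive paths with skip
connections; `n_layers` pooling levels, downsampling factor `2**n_layers`),
and full-resolution `resnet` (identity-skip units), `highway` (sigmoid-gated
units, gate bias −1 toward carry), and `dense` (each layer sees the
concatenation of all earlier feature maps; growth rate 8 by default).
`base_filters` defaults to 32.

Five losses: `square` (mean squared error between sigmoid(scores) and the
target mask), `softmax` (per-pixel cross-entropy across ≥2 channels),
`entropy` (per-channel sigmoid cross-entropy, multi-label), `dice`
(1 − soft Dice with smoothing 10⁻⁶), `logistic` (single-channel sigmoid
cross-entropy).  The canonical organelle configuration is a 9-layer resnet
with the square loss; a 16-layer resnet is the heavier variant.

"Epochs" are gradient steps on randomly cropped patches (batch 4 by
default), not passes over a dataset: with one to ten annotated slices a
dataset pass is not a meaningful unit.  One annotated slice suffices to
train.  Augmentation draws one transform per step uniformly from the enabled
subset of {fliplr, flipud, rot90, transpose} plus identity, applied
identically to image and label patch.  Patches are sampled uniformly; class
balancing (resampling until the patch contains foreground) exists as an
option but is off by default.  The optimiser is Adam at learning rate 10⁻³.
Intensities are standardised per volume (mean 0, sd 1) at both training and
inference time.

Inference tiles each slice with an overlap margin: the slice is
reflect-padded by `overlap`, tiles of side `tile` advance by
`tile − 2·overlap`, and only each tile's central region is written out — a
degenerate weighted-average blend with weight 1 in the centre and 0 in the
margins.  When `overlap` is at least the receptive-field radius (one pixel
per 3×3 convolution; 11 px for the 11-conv 9-layer resnet), the tiled output
equals a whole-slice forward pass exactly away from the image border, which
the tests assert at < 10⁻⁵.  A constant-output model is unchanged by
blending.  Scores pass through the loss's link (softmax for `softmax`,
sigmoid otherwise) to give probabilities in [0, 1].

## Flood-filling 3-D instance segmentation

The FFN is a 3-D residual CNN (default 3 blocks, 12 channels) over an
odd-sided field of view (FOV), taking two channels — standardised intensity
and the current soft object mask (mapped to [−1, 1]) — and emitting per-voxel
membership logits for the object centred in the FOV.

*Preparation.* Training coordinates are all foreground voxels whose centred
FOV fits in the volume, bucketed by the fraction of the FOV occupied by the
centre voxel's object into `n_classes` equal-width classes (exact counts via
an integral image); an equal number per nonempty class is sampled and
shuffled.  This balances easy interior examples against boundary examples.
Coordinates serialise to HDF5 (`centers` N×3, `ids` N, `classes` N).

*Training.* Per step, one FOV example is cut at a coordinate; the mask
channel starts at `seed_prob` (0.95) at the centre and 0.05 elsewhere; the
target is the binary mask of the centre object; the loss is voxelwise
logistic.  The predicted mask is fed back as the mask channel for
`refine_iters` (2) refinement iterations, each treated as its own training
example — gradients are not propagated through the feedback, which keeps
memory flat and is sufficient at this scale.

*Inference.* Seeds are peaks of the Euclidean distance transform of the
thresholded intensity volume (Otsu split, minority side taken as foreground),
ranked by depth, ties broken by (z, y, x); visited voxels are excluded.  Per
seed, the FOV runs the model, writes the refreshed probabilities into the
object's canvas, and enqueues moves of `delta` voxels along each axis whose
face-centre probability reaches `move_threshold` (0.9), never revisiting a
move location for the same object.  When the queue empties, voxels at
probability ≥ `segment_threshold` (0.6) become the object if at least
`min_segment_size` (27) voxels remain unclaimed; earlier objects keep claimed
voxels (first-come priority; no agglomeration afterwards).  Termination is
guaranteed because each FOV centre is enqueued at most once per object.
Default FOV is 17³ with `delta` (4, 4, 4) — a desk-scale reduction of the
33³ FOV used by full-scale flood-filling systems; the tests and acceptance
pipeline use 9³ with `delta` (2, 2, 2) on 32³–48³ volumes.

With a ground-truth membership oracle in place of the model, flood filling
reproduces the 3-D connected components of the reference exactly (instance
RAND = 1), which separates the traversal logic from model quality in tests.

*Postprocessing* compacts ids to 1..K in order of first appearance and
renders a deterministic golden-ratio-hue colour preview.

## Postprocessing into 3-D objects

`binarize` thresholds with the ≥ convention (defaults: 0.5 for probability
maps, 128 for 8-bit images).  `label3d` labels maximal connected components
(6-connectivity by default — conservative for thin EM structures; 26
optional) with ids renumbered in scan order of each component's first voxel.
`watershed3d` partitions a mask from markers by flooding the negative
Euclidean distance transform; markers default to per-component
distance-transform peaks at minimum separation 3.  The distance transform
treats the volume border as background (so a mask filling the array still has
a finite height function) and is anisotropic by default, using the voxel
spacing (a 30 nm z-step counts as five 6 nm pixels); `use_spacing=False`
gives the isotropic voxel-unit transform.  `remove_small` drops objects
below a voxel-count threshold without renumbering.

## Evaluation

With `p_ij` the joint probability that an evaluated voxel carries inferred id
`i` and ground-truth id `j`, and marginals `s_i = Σ_j p_ij`,
`t_j = Σ_i p_ij`, the RAND F-score is

    V_α = Σ_ij p_ij² / (α Σ_k s_k² + (1−α) Σ_k t_k²),   α = 0.5 by default.

The α→0 limit `Σp²/Σt²` is reported as the split score (it drops when the
prediction shatters ground-truth objects); the α→1 limit `Σp²/Σs²` is the
merge score (it drops when the prediction fuses them).  A perfect
segmentation scores 1 at every α.  Foreground-restricted evaluation — the
connectomics-challenge convention — excludes voxels whose ground-truth id is
0; it is on by default and toggleable.  Instance mode compares ids as
objects; semantic mode collapses both volumes to binary first.  Note one
consequence of combining semantic mode with foreground restriction: only
ground-truth-foreground voxels are counted, so an all-background prediction
degenerately scores 1.  The end-to-end tests therefore additionally require
a nonempty prediction, and the overlap trio below is reported alongside.
Jaccard `|A∩B|/|A∪B|`, Dice `2|A∩B|/(|A|+|B|)` and conformity
`(3·Dice − 2)/Dice` (undefined at Dice 0, reported as −inf) complete the
semantic picture.

## Meshes and annotations

Per-object surfaces come from marching cubes at iso-level 0.5 on the
object's binary mask, padded by one background voxel so objects touching the
volume border still close; vertices are scaled to nanometres and ordered
(x, y, z).  Meshes export as OBJ and STL; watertightness and enclosed volume
are checked through the face-adjacency and signed-volume machinery of
`trimesh`.  Annotation tables hold one row per object (name, deterministic
colour, voxel count) plus marker points in mesh space, exported as plain CSV
(`objects.csv`: id,name,r,g,b,voxel_count; `markers.csv`:
object_id,x_nm,y_nm,z_nm,note) and re-readable losslessly.

## Synthetic fixtures

`synthdata` generates the two canonical targets at desk scale.
*Mitochondria mode*: `n_objects` non-overlapping random ellipsoids (in-plane
semi-axes ~5–14 px, flattened in z, random in-plane orientation, 2-voxel
clearance so objects stay separate components), rendered at mean gray 90
against a textured background at 170, with faint sinusoidal cristae-like
stripes inside and Gaussian noise of sd 8 — dark organelles on brighter
cytosol, the qualitative contrast of SEM data.  Placement is rejection
sampling with 100 retries per object; failure raises an error reporting the
achieved count.  *Mosaic mode*: a seeded nearest-neighbour tessellation into
columnar cells with per-slice random-walk drift (sd 0.5 px/slice), membranes
where the two nearest generator points are nearly equidistant
(`membrane_width`), labels 0 on membranes.  Both generators are bit-exact
functions of their seed.

What the fixtures do **not** model: imaging physics, section/staining
artifacts, alignment jitter, anisotropic point-spread, organelle interiors of
neighbouring classes, or the morphological complexity of real neurites.
Passing the end-to-end tests therefore demonstrates that the machinery —
sampling, optimisation, tiling, flood-filling, scoring — is correct and
well-conditioned, not that the default networks reach any particular
accuracy on real EM data, where far longer training on real ground truth is
required.

## Problem sizes and reproducibility

The shipped tests and the acceptance script run everything at fixed seeds and
desk scale, chosen so the full suite completes in minutes on one CPU:

* slice-wise workflow: 20 slices of 256² with 15 ovals; train on 15 slices
  (9-layer resnet, 16 base filters, square loss, 300 steps, patch 64); infer
  the 5 held-out slices tiled at 64/16; semantic RAND plus the overlap trio;
* flood-filling workflow: 2 ellipsoids in 32³; FOV 9³, depth 2, 8 channels,
  500 steps; instance RAND and recovered-object count;
* metric/labeling oracles: 200 random 10³ label pairs, 100 random 20³ masks,
  20 oracle flood fills, 50 watershed fixtures.

`base_filters=16` and the small FFN widths are problem-size choices for the
fixtures' difficulty; the library defaults (32 filters, 17³ FOV) remain the
recommended starting point for real stacks.

## Known limitations

* CPU-only; no multi-GPU, no distributed inference, no pretrained weights.
* FFN training truncates gradients at the mask feedback; full-scale
  flood-filling systems backpropagate through more machinery and train for
  orders of magnitude longer.
* No agglomeration of oversegmentation, no learned z-connectors, no
  border-tolerant metric variants, no variation-of-information.
* The CLAHE slope→clip mapping is this package's documented convention.
* PNG label export is limited to ids < 2²⁴ (use TIFF/HDF5 beyond).
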