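# Methods

## Problem and model

Focal liver lesions are segmented on portal-venous CT, where parenchyma
enhances and most lesions are hypodense but vessels and bile ducts can
mimic lesion intensity on single slices.  Purely 2D networks ignore
through-plane context and confuse vessels with lesions; full 3D networks
are memory-hungry and are usually trained on small crops; conventional
2.5D networks (adjacent slices stacked as input channels) fuse all slices
in the very first convolution, losing slice identity.

The model implemented here is a U-Net whose encoder embeds a small number
of 3D convolutions into a 2D residual trunk:

* **Input.** `k = 7` adjacent slices, windowed to `[0, 1]` with the
  soft-tissue window (level 50 HU, width 400 HU), entering the network as
  a depth axis: `(N, 1, 7, H, W)`.  The prediction is for the central
  slice only; volumes are segmented by sliding the stack.
* **Stem.** One 3D convolution `(3, 7, 7)`, stride `(1, 2, 2)`, depth
  padding 1 (depth preserved at 7), into 64 channels, followed by a
  depth-preserving `(1, 3, 3)` max pool with stride `(1, 2, 2)`.
* **Mixed layers.** Four stages with 3D channels `[64, 128, 256, 512]`,
  block counts `[2, 2, 2, 2]` (deeper variant `[9, 12, 8, 3]`) and depth
  kernels `d = [2, 2, 2, 3]`.  The first block of each stage applies a
  `d x 3 x 3` convolution with no depth padding, so the depth trajectory
  from 7 input slices is `7 -> 6 -> 5 -> 4 -> 2`; stages 2-4 also halve
  the plane.  A global pointwise path — two 1x1 convolutions applied to
  the depth-folded view of the local output — is replicated along depth
  and added to the local 3D map (the 3D residual connection).  The fused
  map is folded to 2D (`C' = C x D`) and passed through the remaining
  blocks: inverted-bottleneck residual units (1x1 expand to 4x the
  stage's 3D channel count, depthwise 3x3, 1x1 project back to `C'`).
  The stage output concatenates the last block with the first block's
  folded map, doubling the width handed to the decoder skip and to the
  next stage, where it is re-viewed as a 3D map with twice the channels.
* **Decoder.** Five blocks with channels `[256, 128, 64, 32, 16]`, each a
  nearest x2 upsampling followed by two 3x3 convolution + batch norm +
  ReLU pairs.  Skips come from the four stage outputs (2D views) and, at
  the H/2 level, from the central depth slice of the stem activation.
  The head is a 3x3 convolution with sigmoid; the binarization threshold
  (default 0.5) lives in the inference engine, not the model.

A conventional 2.5D baseline is provided for comparison: a standard
18/50/101-layer residual encoder whose first convolution is widened to 7
input channels, with the same style of U-Net decoder.

### Parameter accounting

Published totals for this family are reproduced exactly by the
implementation for the default mixed network (29,634,065 -> 29.6 M) and
for the three 2.5D baselines (14,340,753 / 32,533,649 / 51,525,777 ->
14.3 / 32.5 / 51.5 M), using bias-free convolutions with affine batch
norm throughout and the decoder convention above.  Free details that the
architecture description leaves open (stem depth kernel, global-path
hidden width, residual block internals, skip convention) were resolved by
a systematic search over the documented alternatives against those
printed totals; the resolution is the configuration described above, with
the global pointwise path running at the stage's 3D channel count.

The deeper variant is irreconcilable jointly with the default: the two
totals differ only through the extra `(7, 10, 6, 1)` 2D blocks, whose
summed parameters would need to be 27.0 M (+/- rounding) for both totals
to hold, and no self-consistent reading of the block design reaches that
value (the candidate families give 24.7-25.1 M, 27.13 M, or well above
27.6 M).  The implementation therefore reports its honest computed total
for the deeper variant, 54,570,001 (54.6 M).

## Loss

`L = L_Tversky + lam * L_BCE` with `alpha = 0.3` (false positives),
`beta = 0.7` (false negatives), `lam = 0.6`.  Soft counts are computed on
sigmoid probabilities.  The smoothing constant defaults to 1.0 in both
numerator and denominator.  On lesion-free slices the Tversky gradient
collapses (verified by numeric differentiation in the tests); the
cross-entropy term keeps such slices informative.  Cross-entropy is a
mean over pixels and batch, with predictions clipped at 1e-7.  The loss
is pooled over the whole batch of central-slice predictions.

## Training and inference

Adam (beta1 0.9, beta2 0.999) with cosine annealing and warm restarts:
initial rate 2e-4, floor 1e-6, restart period 300 iterations with growth
factor 1.  Batches draw random (case, slice) pairs, half of them from
lesion-bearing slices; each sample receives one random in-plane rotation
in [-30, +30] degrees applied identically to every slice of the stack
(bilinear) and to the mask (nearest, re-binarized).  Intensities are
standardised with cohort-level mean/sd of windowed intensities, computed
at the start of training and stored with the run.  Inference slides the
7-slice stack over every slice index (edge replication at the volume
boundaries) and binarizes at 0.5.

The compute core is a small reverse-mode autodiff engine on numpy arrays
(im2col convolutions, explicit backward passes), written for exactly the
operations these networks need; it is single-threaded, float32 and fully
deterministic, which gives bit-reproducible phantom -> train -> evaluate
runs for fixed seeds.

## Synthetic phantoms

The generator emulates desk-scale portal-venous liver CT: a textured
parenchyma background (110 +/- 10 HU), one to three hypodense lesions
(55 +/- 10 HU) shaped as ellipsoids with semi-axes drawn from 6-18 mm and
irregular boundaries produced by smooth radial perturbation (relative
amplitude 0.15), two to four hyperdense random-walk vessel tubes
(150 +/- 10 HU, radii 1.5-3 mm) that are absent from the ground-truth
mask, and additive Gaussian acquisition noise (10 HU).  The default grid
is 16 x 96 x 96 voxels at 2.5 x 1.5 x 1.5 mm — a cropped liver
subvolume sized for CPU experiments; full 512 x 512 planes are supported
but not exercised by the tests.  What the phantom does *not* model:
anatomical liver shape, CT reconstruction physics, multi-phase contrast
dynamics, lesion texture heterogeneity, and neighbouring organs.
Passing tests therefore demonstrate that the pipeline learns to separate
hypodense lesions from parenchyma and bright distractors under noise —
not clinical-grade performance on patient data.

## Numerical choices and degenerate inputs

* Plane sizes must be multiples of 32 (five encoder halvings); batch norm
  needs more than one element per channel, so the practical minimum plane
  is 64 x 64.
* Stack extraction replicates edge slices rather than zero-padding, so
  the 3D stem never sees artificial empty slabs.
* Masks are validated as strictly binary at every interface; a case with
  an empty reference mask is flagged undefined and excluded from
  aggregation with a warning.
* Cohort confidence intervals are percentile bootstrap over cases (2000
  replicates, seed-controlled).  With ~30 cases its empirical coverage is
  close to but slightly below nominal, which the calibration test
  tolerates (+/- 2%).
* Weight initialisation is Kaiming-normal from a dedicated stream, so
  models are reproducible from a build seed independently of any global
  random state.

## Desk-scale experiment sizes

The self-contained end-to-end experiment trains the quarter-width model
(stem 16, stages [16, 32, 64, 128], decoder [64, 32, 16, 8, 4]) for 600
iterations at batch size 8 on 20 phantoms of 12 x 64 x 64 voxels and
evaluates on 10 held-out phantoms.  Batch size 8 is the largest that
keeps the three-seed experiment inside a single-core test run (the
full-scale configuration uses 16); the phantom grid was likewise sized
for CPU runtime.  At this budget the network reliably finds the lesions
(sensitivity near 99%) while probability calibration at the 0.5
threshold is still tightening.

## Known limitations

* The deeper-variant parameter total cannot match its published value
  jointly with the default variant (see "Parameter accounting").
* No surface-distance metrics (HD95/ASSD), no lesion-instance detection
  statistics, no multi-class heads, no DICOM ingestion.
* Training is single-threaded numpy; it is meant for desk-scale
  validation, not for full-scale 512 x 512 training runs.
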