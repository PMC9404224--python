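# Methods

`breastseg` implements an automatic pipeline for breast-tumor segmentation
and volumetry on subtraction DCE-MRI-like volumes: a 3D Res-UNet trained
with a combined Dice/cross-entropy objective, sliding-window inference with
rotation test-time augmentation (TTA) and checkpoint ensembling, small-
component post-filtering, radiomics-style shape quantification, Otsu-based
cystic/necrotic decomposition, AJCC-style T staging, and DSC/IOU/ICC
evaluation. Because clinical DCE-MRI cohorts are not redistributable, the
package ships a phantom generator that emulates the statistical structure
such a pipeline assumes, with closed-form ground truth; every empirical
claim in the test suite and the acceptance script is computed on those
phantoms at run time.

## Phantom model

A lesion is a rotated triaxial ellipsoid with semi-axes `a >= b >= c` (mm)
on an anisotropic voxel grid, default spacing (0.7, 0.7, 1.1) mm (thicker
axial slices, as in typical breast protocols). Voxel membership is a
voxel-center-inside test — no partial volume — which matches the discrete
mask semantics used by every downstream shape feature. Intensities sit on
an arbitrary scanner-like scale: background 50, enhancing lesion 300,
optional hypointense core 100, plus iid Gaussian noise (default SD 20, i.e.
8% of the lesion-background contrast). The background carries no anatomical
texture; passing tests therefore demonstrate correctness of the machinery
on high-contrast enhancing masses, not clinical performance on real breast
tissue (no coil inhomogeneity, no enhancing parenchyma, no multifocality).

Optional lobulation perturbs the radial boundary with a random degree-2/3
spherical-harmonic field normalized to unit maximum, scaled by an amplitude
in [0, 0.3]; closed-form geometry then no longer applies and the analytic
fields are reported as NaN. `analytic_geometry` refuses lobulated specs.

Simulated cohorts draw the longest diameter `2a` uniformly within each
stage's size band, with a 2 mm guard away from the 20/50 mm staging
boundaries — more than one voxel diagonal (1.48 mm at default spacing) — so
the true stage survives digitization; axis ratios `b/a ~ U(0.6, 0.9)`,
`c/b ~ U(0.6, 0.95)` and uniform random orientations. Stage counts follow
largest-remainder rounding of the requested mix.

## Preprocessing

Each case is resampled to the cohort's mean voxel spacing (trilinear for
images, nearest-neighbour for masks — nearest keeps masks binary), then
normalized per case: intensities are clamped to the [0.5, 99.5] percentile
range and z-scored with the mean/SD of the clamped volume. Normalization is
applied after respacing, and statistics are taken over the whole clamped
volume, not the foreground only. A constant volume maps to zeros through an
SD guard of 1e-8. Training patches (default 96^3; each dimension must be a
multiple of 2^(depth-1)) are centered on a uniformly drawn foreground voxel
with probability `fg_center_prob` (default 0.5; a 2:1 foreground bias is a
supported configuration), otherwise on a background voxel; centers are
clipped so patches fit inside the zero-padded volume, which slightly
jitters centers near borders. Augmentation applies, each with its own
probability: random zoom in [0.9, 1.1], intensity scale in [0.9, 1.1],
intensity shift in [-0.1, 0.1] (normalized units), Gaussian noise with SD
up to 0.1, in-plane 90-degree rotations, and a smooth random elastic
deformation (Gaussian-filtered displacement, sigma 6 voxels, amplitude 2
voxels). Geometric transforms move image and label together with nearest
interpolation for the label; intensity transforms touch the image only.
The magnitudes are deliberately conservative defaults; none is prescribed
by the task and all are configurable.

## Network, loss, optimization

The Res-UNet is implemented in pure NumPy with hand-written
backpropagation (src/breastseg/nn). Encoder levels are residual blocks —
two convolution/instance-norm/ReLU stages whose input is added to their
output, through a 1x1 projection when channels change — with strided
3x3x3 convolutions halving resolution between levels; the decoder uses
kernel-2/stride-2 transposed convolutions, concatenates the same-level
encoder feature (the U-Net skip), and refines with two plain conv-norm-act
stages; a 1x1 head emits two-class scores at input resolution. Channels
double per level from `base_channels`. Convolutions are evaluated as one
BLAS matrix product per kernel offset, which keeps memory flat; the layer
dtype is float32 by default and switchable to float64, which the test
suite uses to verify the whole backward pass against a central-difference
directional derivative at 1e-5 relative tolerance.

The objective is `0.5 * dice + 0.5 * cross-entropy`: soft Dice of the
foreground softmax channel pooled over the batch with smoothing term 1e-5
(so empty-target patches cannot divide by zero), plus mean per-voxel
negative log softmax probability of the true class. A two-channel softmax
head is used rather than a single sigmoid, and Dice is computed on the
foreground channel only. Optimization is Adam (default lr 1e-3, batch 2),
iterating patch sampling, augmentation, forward, loss, backward, step; an
"epoch" is a fixed number of patch iterations, since patch-based sampling
has no natural dataset pass. Training is bit-reproducible under a fixed
seed. Checkpoints store the parameter arrays with the architecture spec
and a configuration hash.

## Inference and post-processing

Whole volumes are tiled with overlapping windows (default overlap 0.5,
uniform stitching weights) and per-voxel class probabilities are averaged
over covering windows; volumes smaller than the patch are padded and
cropped back. TTA repeats the inference on copies rotated by 90/180/270
degrees in the axial plane (padding to square in-plane when needed),
un-rotates each probability map, and averages with the identity pass at
the probability level — arithmetic mean rather than majority vote, a
choice the tests pin down with an exactly rotation-equivariant operator.
A checkpoint ensemble is the unweighted mean of member maps. The final
mask is the per-voxel argmax from which foreground connected components
(26-connectivity, configurable to 6) with fewer than 30 voxels are
removed; a component of exactly 30 voxels survives, the filter is
idempotent, and an empty result is legal (small lesions may be missed
entirely).

## Quantification and staging

Shape features are computed on the largest connected component (ties break
to the component containing the lexicographically smallest voxel index),
in world millimetres via `world = origin + index * spacing`:

* maximum 3D diameter — the largest pairwise Euclidean distance between
  foreground voxel centers (surface voxels suffice; the implementation
  prunes to convex-hull vertices, with a brute-force fallback for
  degenerate point sets);
* maximal/minimal diameter — `4 * sqrt(lambda_1)` and `4 * sqrt(lambda_2)`
  for the leading eigenvalues of the foreground coordinate covariance (the
  standard radiomics major/minor axis lengths). For a uniform solid
  ellipsoid this converges to `4a / sqrt(5)`, not `2a`; tests therefore
  check against an independent eigen-decomposition, not against `2a`;
* mesh volume — the divergence-theorem volume enclosed by the marching-
  cubes iso-surface at level 0.5 of the zero-padded binary mask, with
  spacing-aware coordinates;
* voxel volume — exactly foreground count times the per-voxel volume.

Cystic/necrotic decomposition thresholds the in-lesion intensity histogram
with Otsu's criterion: an exhaustive search over the interior edges of a
128-bin histogram spanning the in-lesion range, minimizing the within-class
variance (equivalently maximizing between-class variance). When empty bins
make the objective flat across the gap of a well-separated bimodal
histogram, the midpoint of the tied plateau is returned, so the threshold
lands mid-gap rather than hugging the dark mode. Voxels below the threshold
form the cyst candidate; components under 30 voxels are removed. A
near-constant histogram yields "no cystic component" rather than an error.

T staging classifies a diameter as T1 (<= 20 mm), T2 (20-50 mm, inclusive
above) or T3 (> 50 mm). The clinical size bands are ambiguous exactly at
both cut-offs; the package fixes the AJCC-consistent inclusive-upper-bound
reading and documents it in `StagingRules`. The staging feature defaults to
the maximal (major-axis) diameter and is switchable to the maximum 3D
diameter; ground-truth phantom stages are defined from the generative `2a`,
which the maximum 3D diameter of the digitized mask recovers to within one
voxel diagonal, so truth-mask staging uses that feature.

## Evaluation

Per-case overlap uses DSC and IOU on foreground voxel sets, with the
identity `DSC = 2*IOU/(1+IOU)` enforced in tests to 1e-12. Both masks empty
scores 1 with a warning (a documented convention); exactly one empty scores
0. Staging performance is a 3x3 confusion matrix with one-vs-rest
precision, recall (sensitivity), specificity and F1 per class, macro
averages over classes defined in the truth (undefined entries are NaN,
never silently dropped), and support-weighted averages (weighted recall
equals accuracy by construction). Agreement between predicted and
reference measurements uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1) — absolute agreement
penalizes systematic offset, the right behaviour when an automatic reading
replaces a manual one — via `pingouin.intraclass_corr`, cross-checked in
the tests against the closed-form two-rater ANOVA decomposition.
Concordance bands: excellent above 0.95, good above 0.80.

## Scaled-down study sizes

All empirical checks run on a single CPU. The training study uses 40
training and 10 held-out phantoms on 48^3 grids (one sliding window per
volume), a depth-3/base-8 network (~120k parameters), 48^3 patches, batch
2 and 300 iterations — about ten minutes — and asserts held-out mean DSC
of at least 0.80, that TTA costs at most 0.02 DSC, and that the
3-checkpoint ensemble is no worse than its weakest member by more than
0.02. Smaller toy runs (depth-2/base-4, 32^3 patches) back the
behavioural tests. These sizes demonstrate that the pipeline learns,
stitches, augments and measures correctly; they make no claim about
clinical-scale accuracy.

## Known limitations

* The phantom background is homogeneous noise; false-positive behaviour on
  structured parenchyma is untested by construction.
* Multifocal/multicentric disease and non-mass enhancement are out of
  scope; quantification deliberately measures the largest component only.
* The NumPy network trains at CPU scale; the architecture is configurable
  but no claim of identity with any particular published network instance
  is made.
* DICOM ingestion and subtraction-image computation are out of scope;
  inputs are already-subtracted NIfTI volumes.
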