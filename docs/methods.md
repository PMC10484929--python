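# Methods

This note documents the models and numerical choices behind `brainfrac`:
what each stage computes, what the synthetic phantoms do and do not emulate,
and where the design was genuinely open.

## Voxel classification model

The measurement chain treats a two-channel light-sheet stack (z step 3.5 um,
in-plane pitch 5 um by default; the in-plane pitch of the modeled
acquisition is not published, so it is a free configuration value) as:

* autofluorescence channel = brain body, used only for masking;
* signal channel = smooth background + stained puncta + additive noise.

Steps, with defaults in `VoxelClassifierParams`:

1. **Brain mask** — slicewise Gaussian blur, sigma 10 vx, thresholded at a
   user-set value (there is no principled default; `--auto-otsu` is an
   explicit opt-in), largest connected component kept. An empty mask is an
   error, not an empty result.
2. **Noise sigma** — `(P84 - P16)/2` of the *raw* signal-channel voxel
   values inside the mask (the +/-1 sigma band of a Gaussian). Percentiles
   use linear interpolation between order statistics. For pure N(0, s)
   data this estimates `0.9945 s`. Two deliberate properties: it is taken
   before filtering (the stated order of operations; a
   `sigma_on_filtered` flag exists for sensitivity analyses), and it is
   contaminated upward by the bright stained tail — at ~1.7% stained
   volume the estimate runs ~7% high, which is part of the measured
   method, not a bug.
3. **Band-pass** — high-pass (subtract sigma-6 blur) then low-pass
   (sigma-1 blur). All sigmas are in-plane only (2D filtering per z-slice):
   the method is specified in xy voxels and the z spacing differs from the
   xy pitch. The filter is linear and annihilates constants.
4. **Classification** — one-sided: a voxel is positive iff its band-passed
   value exceeds `k_sigma = 2` noise sigmas (the signed value, not the
   magnitude; dark responses never count) and it carries an atlas label.
5. **Volume fractions** — positive/total voxels per region, with "whole
   brain" defined as the union of atlas regions, so whole-brain counts are
   the sums of regional counts by construction.

## Atlas interpolation

Sparse per-plane annotations (e.g. 50 horizontal planes out of ~100) are
densified by shape-based interpolation: per region, a 2D signed Euclidean
distance map (negative inside) on each annotated plane; linear interpolation
of distances between consecutive annotated planes; each voxel takes the
region of the most negative interpolated distance, or 0 if none is
negative. A region absent from a plane gets distance +1e6 ("infinitely
outside"). Ties break toward the lower region id (argmin order), for
determinism. Annotation groups on different axes are merged, later groups
overriding earlier ones inside their annotated extent but only where they
assign a nonzero label — coronal cortex subdivisions refine, rather than
erase, the horizontal base atlas. The published description of the original
reconstruction says only that it interpolated; signed-distance
interpolation is this package's documented substitute, chosen because it
produces smooth boundaries from sparse planes and is analytically testable
(concentric circles interpolate linearly in radius; a straight shared
boundary translates linearly, leaving no unlabeled gap).

## Registration

One landmark line per brain. `theta = angle(ref) - angle(sample)` in the
(y, x) plane, `scale = |ref| / |sample|` of the in-plane lengths, and the
translation maps the transformed first endpoint onto the reference's. The
rotation axis is z only (flat-landed assumption). Whether the original
workflow scaled z by the same in-plane factor is unspecified; here
isotropic z scaling is the default with a `scale_z` flag. Resampling is
inverse-mapped (`scipy.ndimage.affine_transform`), trilinear for
intensities, nearest for labels, zeros outside. Rotation-matrix entries
within 1e-12 of 0/+/-1 are snapped so quarter turns are exact grid
permutations.

A practical caveat the tests document: registration interpolates, which
smooths acquisition noise, so a percentile noise sigma estimated on a
registered stack is smaller than on native data and the 2-sigma contour is
correspondingly more liberal. The cohort pipeline therefore simulates
aligned acquisitions by default; the `misalign` option exercises the full
mis-pose -> landmark -> resample chain and is tested only up to this known
bias.

## 2D cell detection

The detector follows a particle-counting parameterization in physical
units: optional median filter (radius 0 = off), Gaussian high-pass with
sigma 8 um / 0.645 um/px, local-mean binarization over a *disk* of radius
25 px ("radius" terminology; not a square window), 8-connected components,
area filter 15-140 um^2, circularity filter 0.1-1.0 with
`circularity = 4 pi A / P^2` using the Crofton perimeter estimator clipped
at 1.0 (naive edge counting underestimates disks), and minimum-distance
suppression keeping the larger area (ties toward the lower (row, col)
centroid). Offset convention: a pixel is positive iff
`value > local_mean - offset`, so the conventional offset of -30 demands
`value > local_mean + 30`. The local mean is border-normalized, making
detection invariant to adding a constant to the image.

Colocalization automates what was a manual count: a cell is
marker-positive iff at least `overlap_fraction = 0.5` of its pixels exceed
the marker channel's local-mean threshold (the same rule as detection).
The exact overlap criterion of a human rater is unknowable; the fraction is
exposed, not claimed faithful. One corollary of using a purely local rule:
a *uniformly* saturated marker channel has no local contrast and scores 0%,
exactly like a blank one — marker calls require local contrast, which real
stained cells have.

Layer assignment bins detected centroids into half-open row intervals
`[b_i, b_{i+1})` from externally supplied boundaries (drawn from a nuclear
stain in the modeled workflow; automatic layer delineation is out of
scope). Cells outside the outermost boundaries go to a reported sentinel
layer.

## Statistics

* **Mann-Whitney**: `U = #{x_i < y_j} + 0.5 #{ties}`. For `n1 + n2 <= 25`
  and untied data the null is exact: the number of labelings with statistic
  u equals the number of partitions of u into at most n1 parts each at most
  n2 (Gaussian-binomial coefficients), computed by the standard two-way
  recurrence in exact integer arithmetic. The two-sided p is
  `2 min(P(U <= u), P(U >= u))` capped at 1 — this convention reproduces
  the printed values of the modeled study (e.g. `p = 24/8008 = 3.00e-3`
  at n=6/10, U=4). Ties or larger samples fall back to the
  normal approximation with tie-corrected variance and continuity
  correction, flagged in the result.
* **Friedman + Dunn**: within-row mid-ranks;
  `chi2 = 12/(nk(k+1)) sum R_j^2 - 3n(k+1)` against chi-square(k-1); Dunn
  `z = |Rbar_i - Rbar_j| / sqrt(k(k+1)/(6n))`, two-sided normal p times
  `k(k-1)/2` (Bonferroni), capped at 1. Complete rows are required; the
  modeled study reports a "paired" three-condition analysis with unequal
  group sizes, which this module deliberately rejects rather than guesses
  at.
* **Shapiro-Wilk** delegates to scipy; constant samples are degenerate and
  raise. Summaries: median [IQR] with linear-interpolation percentiles, or
  mean with sample s.d. (n-1).
* No multiple-testing correction across regions by default (matching
  per-region reporting); Benjamini-Hochberg is available behind the
  pipeline's `fdr` flag.

## Synthetic phantoms and ground truth

**3D.** An ellipsoid (default semi-axes 36 x 52 x 52 vx inside a
96 x 128 x 128 grid) partitioned into 7 connected regions: a core
(elliptical radius < 0.45) halved into diencephalon and hippocampus, and
five angular shell sectors sized so the neocortex is the largest region
(140 degrees of the shell). The exact geometry is a free design choice; what
matters downstream is that regions are connected, non-empty and partition
the brain. Stained signal is a sum of isotropic Gaussian blobs
(sigma 2 vx); ground truth defines a voxel positive where the noise-free
blob field exceeds half the blob amplitude, giving an unambiguous
half-maximum ball of radius `sigma sqrt(2 ln 2) = 2.35` vx per blob. Blobs
are planted at uniform sub-voxel centers inside each region until the
region's exact positive count reaches its target within half a blob volume;
requests above 50% density are rejected (the phantom stops being punctate).
Truth fractions are stored from exact voxel counts of the final mask.
Background is smooth across the brain boundary in the signal channel — a
hard intensity step at the brain edge would dominate the high-pass response
with an artefactual bright ring; the brain body lives in the
autofluorescence channel instead. Real stacks do fall off at the tissue
boundary, so passing tests say nothing about edge handling on real data.
Also not emulated: PSF anisotropy, stripe artifacts, vignetting,
intensity falloff with depth.

**Amplitude calibration.** The half-maximum truth contour and the
2-noise-sigma measurement contour coincide only at one amplitude. For an
isolated sigma-2 blob the single-blob calibration gives amplitude
~5.5 noise sigmas, but two density-dependent terms of the full chain shift
the operating point: the percentile noise sigma is inflated by the stained
tail, and the high-pass subtracts the blob field's local mean (each blob
sits in the negative moat of its neighbours). The default amplitude
(60 = 6 noise sigmas) is therefore calibrated by simulation with the full
chain at the median whole-brain density of the modeled study
((0.507% + 1.63%)/2): at that density the measured/planted volume ratio is
1.00. The residual density dependence leaves the control group measured
~+14% and the treated group ~-8% relative to truth — well inside the 25%
recovery tolerance the tests assert, and a faithful property of a
fixed-threshold method applied across densities.

**Cohorts.** Group targets put the study's regional medians (in % of
region volume: neocortex 0.676 -> 2.47, striatum 0.471 -> 1.38,
metencephalon 0.564 -> 1.18) on the three effect regions and solve a common
fraction for the remaining regions so the volume-weighted whole-brain
fractions hit 0.507% and 1.63%. Per-animal variability is one lognormal
factor (`sigma_log = 0.15`) *shared across regions within an animal* —
staining efficiency and exposure vary at the animal level — rather than
independent per-region draws; fractions are positive and right-skewed under
this model. A consequence worth knowing: per-region group tests on a null
cohort are strongly dependent (an animal high in one region is high in
all), so the familywise false-flag rate across the 8 tests stays near the
per-test level instead of inflating eightfold.

**2D.** Cells are filled disks (default radius ~4-4.5 px, amplitude 150
over background 20, noise sigma 3) drawn in every channel they belong to;
truth tables carry the rasterized pixel count times `0.645^2` um^2 (a
radius-4 disk at an integer center covers 49 px = 20.4 um^2), the
rasterized Crofton circularity, the layer from the supplied boundaries and
the channel memberships. Planted cells closer than their radii plus 2 px
raise an error so truth stays unambiguous. Nuclei (for layer drawing) are
not rendered; layer boundaries are inputs.

## Problem sizes in the test suite

Module tests run on a 32 x 48 x 48 phantom (semi-axes 12 x 18 x 18). The
cohort-recovery suite runs the full 96 x 128 x 128 geometry, 6 + 10 animals
per cohort, 20 seeded effect cohorts and 20 seeded null cohorts; one cohort
takes a few seconds, the whole recovery suite a few minutes. The acceptance
script runs one cohort plus three 2D slices.

## Known limitations

* The measured volume fraction depends on the amplitude/noise operating
  point; the calibration above is specific to sigma-2 blobs and the default
  filter sigmas. Changing any of these re-opens the calibration.
* The exact Mann-Whitney path requires untied data; measured fractions are
  ratios of integers and do occasionally tie in small regions, silently
  switching those comparisons to the flagged normal approximation.
* Signed-distance interpolation cannot represent topology changes between
  annotated planes (a region splitting in two interpolates through a
  pinch).
* The brain mask's sigma-10 blur erodes small objects; phantoms much
  smaller than the default geometry measure masks several percent below the
  analytic ellipsoid volume.
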