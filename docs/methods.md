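# Methods

This note documents the models, conventions and numerical choices behind
`npcradiomics`, in the order the pipeline runs them. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort

The study the package is built around — in-field-recurrent (IFR) vs
non-progressing (NPD) nasopharyngeal tumors on pre-treatment fat-suppressed
T2-weighted MRI — does not come with distributable images, so the cohort is
synthetic and the ground truth is known by construction.

**Texture model.** Each tumor image is a stationary Gaussian random field:
white noise convolved with an isotropic Gaussian kernel whose physical
width is the class's correlation length, rescaled to unit marginal variance
analytically (by the kernel's root-sum-of-squares, not empirically — so the
within-ROI variance of a single realization still collapses in the
infinite-kernel limit, as it must). The field is scaled and offset to a
plausible arbitrary intensity scale (offset 300, amplitude 60, additive
noise SD 15) and the ROI is an ellipsoid (default semi-axes 9 mm) centered
in a 48 × 48 × 12 grid of 0.65 × 0.65 × 4 mm voxels, the acquisition
geometry of the motivating protocol. Class sizes default to 11 IFR + 16
NPD. The correlation lengths default to 4 mm (IFR, coarse heterogeneity)
vs 1 mm (NPD, fine), a deliberately well-separated pair: the synthetic
cohort's job is to exercise and power-test every downstream operator, not
to calibrate clinical effect sizes. This is the simplest process with one
controllable heterogeneity scale; it is a stand-in, not an inference about
NPC biology. It reproduces none of the structured features of real tumor
MRI (anatomy, bias fields, necrotic cores, partial-volume edges), so
passing tests demonstrate correctness and statistical power of the
*pipeline*, never clinical performance.

Every case is a pure function of `(seed, class, index)` through an
independent `SeedSequence` stream, so enlarging the cohort never reshuffles
existing cases.

**Second observer.** Repeat delineation is emulated by a smooth random
radial displacement of the contour: the signed Euclidean distance to the
boundary is compared against a Gaussian-smoothed (4 mm) random field scaled
to typical amplitude `magnitude/2` and hard-clipped at `magnitude`
(default 1 mm). The largest 6-connected component is kept so observer
masks stay single objects.

**Dose cases.** The dose grid is a smooth radially decreasing field around
a focus offset from the recurrence sphere; the 95% isodose radius is placed
at the voxel-count quantile boundary closest to the requested coverage
fraction, so the achieved fraction is exact up to voxel-count resolution
and is stored as ground truth (the generator refuses configurations where
the nearest achievable fraction misses the target by more than 0.02).

## Preprocessing

Order is fixed: resample first, then normalize/quantize. (Quantized levels
cannot be meaningfully interpolated; normalizing on the analysis grid
preserves the [m − 3s, m + 3s] semantics there.)

- **Resampling** to 1 mm isotropic voxels: tricubic B-spline for the image,
  trilinear + 0.5 threshold for the mask (nearest-neighbour stair-steps
  corrupt shape features). The input is first extended by 12 voxels of
  linear extrapolation so the spline prefilter's boundary condition cannot
  perturb interior values; interior reproduction of polynomial fields up
  to degree 1 is then exact to ~1e-7.
- **Normalization/quantization**: m and s are the ROI mean and SD; voxels
  outside [m − 3s, m + 3s] are excluded (no level); the window is split
  into 64 equal-width bins, right-closed at the top, levels 1..64. A
  constant ROI (s = 0) maps everything to level 1 with a warning so
  entropy-type features hit their analytic 0. Quantization is invariant
  under positive affine intensity maps, which is what makes texture
  features comparable across contrast/brightness settings. Excluded voxels
  are dropped from intensity/texture statistics but kept in the mask for
  shape features (shape is geometry, not intensity). Whether the original
  normalization used a fixed bin count or fixed bin width is
  underdetermined by "quantized to 6 bits (between 1 and 64)"; fixed bin
  count 64 over the window is adopted.

## Derived images

- **LoG** at σ = 0.5 / 1.5 / 2.5 mm, separable implementation (sampled
  Gaussian-second-derivative along one axis, Gaussian along the others,
  summed over axes), reflection boundary. The second-derivative taps are
  recentered to exact zero sum so constants (and by symmetry, ramps) are
  annihilated to machine precision. σ below half a voxel triggers an
  under-resolved warning.
- **Wavelet**: one-level undecimated 3-D transform with Coiflet-1 analysis
  filters (the convention of the widely used extraction platforms),
  applied as centered circular separable convolution. Undecimated output
  keeps the derived image congruent with the mask; the periodic boundary
  makes the operator exactly translation-equivariant. Sub-band letters map
  to array axes in index order, first letter = axis 0 (H = high-pass), and
  this convention is recorded in the derivation tags because "HLL" has no
  universal axis convention.

Each derived image is re-normalized and re-quantized inside the contour
before texture computation, since LoG and wavelet responses live on their
own intensity scales.

## Feature manifest (1117)

Per case: 13 shape + 18 first-order + 74 texture on the original image
(105), and 18 + 74 = 92 on each of the 11 derived images; 105 + 11 × 92 =
1117. The family cardinalities (GLCM 23, GLRLM 16, GLSZM 16, GLDM 14,
NGTDM 5) are the standard sets of the established extraction platforms and
are fixed so the manifest total is exact. Keys follow
`family_Abbrev` / `<derivation>__family_Abbrev` (e.g. `glcm_CT`,
`W_HLL__gldm_DE`, `LoG_1.5__F_RMS`); the machine-readable abbreviation map
is `npcradiomics.features.ABBREVIATIONS`. Legacy abbreviation collisions
are resolved as: `glcm_CT` = cluster tendency, `glcm_CP` = cluster
prominence, `glcm_IMC` = informational measure of correlation 1 (IMC2 is
also computed under its own key), `gldm_DE` = dependence entropy,
`gldm_SDLGLE` = small-dependence low-gray-level emphasis, `F_RMS` =
first-order root-mean-square.

Conventions that matter for comparability:

- The gray-level axis of every texture matrix spans 1..64 always, not the
  observed levels, so features are comparable across cases.
- GLCM/GLRLM: 13 unique 26-connectivity directions at distance 1; each
  matrix is normalized per direction (GLCM symmetrically, both pair
  orders); each feature is evaluated per direction and the unweighted mean
  over directions is reported.
- GLSZM is computed once per image — size-zone matrices have no direction
  parameter (a "13 angles" qualifier sometimes attached to GLSZM is a
  carry-over from the run-length family).
- GLDM: 26-neighborhood, Chebyshev distance 1, zero gray-level tolerance;
  dependence size = number of dependent neighbors + 1 (the center), so it
  is always ≥ 1.
- NGTDM: mean over the in-ROI 26-neighbors; voxels with no in-ROI neighbor
  are dropped; coarseness of a degenerate (zero-denominator) field is
  capped at 1e6.
- Logarithms are base 2. Degenerate conventions (constant ROI): GLCM
  correlation = 1, IMC1 = 0, NGTDM contrast/busyness/complexity/strength
  = 0, first-order skewness/kurtosis = 0.
- Shape: volume is voxel-counted; the surface is a marching-cubes mesh of
  the binary mask smoothed with 10 Taubin iterations (raw binary meshes
  overestimate a ball's area by ~9%; the smoothed mesh is within ~1%), and
  sphericity is clipped at its analytic bound 1. Principal axis lengths
  are 4·sqrt(eigenvalue) of the voxel-coordinate covariance; maximum 2-D
  diameters are reported per orthogonal plane.

Every texture family and the first-order set are validated against
independent loop-style brute-force oracles (pair enumeration, run walking,
flood fill, neighbor counting) to 1e-10 relative error; the acceptance
script re-measures this on 50 random ROIs.

## Recurrence dosimetry

`fraction_in_isodose` is the recurrence-volume DVH evaluated at the isodose
level: voxel count with dose ≥ 0.95 × prescription over total mask voxels.
The dose threshold is inclusive (an isodose surface contains its level) and
the fraction is voxel-counted — after isotropic resampling all voxels carry
equal volume, and sub-voxel weighting would be spurious precision.
Classification boundaries are left-closed: fraction 0.95 is in-field ("95%
or more"), 0.20 is marginal ("20 to 95%"). Registration of V_recur onto
the planning grid is an input contract, not a computation (the package
consumes pre-registered masks).

## Selection cascade

Fixed order ICC → PCC → KW/BH → ROC; each stage sees only the previous
stage's survivors.

- **ICC**: two-way random effects, absolute agreement, single measures
  (ICC(A,1)) — the standard form for rater reproducibility; features below
  0.8 are removed, undefined ICCs (no between-subject variance) are
  removed with a warning. The cascade applies ICC to all 1117 features
  using the perturbed-contour second observer.
- **PCC pruning**: while any retained pair has |r| ≥ 0.80, the
  most-correlated pair is taken and the member with the larger mean
  absolute correlation against the retained set is removed; exact ties
  break lexicographically (later key removed). Deterministic by
  construction; validated against an independent re-implementation.
- **Kruskal-Wallis** with tie correction and the χ² approximation (df = 1)
  — standard at n ≈ 27; identical-valued features get p = 1 by the H = 0
  convention. **Benjamini-Hochberg** step-up adjustment; significance is
  gated on the adjusted p < 0.05 (both raw and adjusted values are
  reported, since reporting conventions differ).
- **ROC**: AUC = rescaled Mann-Whitney U with half credit for ties,
  oriented so AUC ≥ 0.5; Hanley-McNeil standard error; 95% CI truncated to
  [0, 1]; sensitivity/specificity at the Youden-optimal threshold with
  ties resolved toward the lower threshold.

## PCA and classifiers

Features are standardized (population SD) before the eigendecomposition;
the smallest k with cumulative explained variance ≥ 0.85 is retained, and
component signs are fixed by making each loading's largest-magnitude entry
positive. Constant features are a hard error (they must be removed
upstream).

Classifier defaults, exposed in the config: ANN = one hidden layer of
⌈(k + 2)/2⌉ logistic units trained by SGD (learning rate 0.3, momentum
0.2, 500 epochs); KNN with k = 3 on Euclidean distance; linear-kernel SVM
with C = 1. Folds are stratified deterministically (class-wise round-robin
after a seeded shuffle — balanced for 11 + 16 cases in 10 folds, with
every minority case in a distinct fold) and metrics come from the pooled
confusion matrix: support-weighted TP/FP rate, precision and F-measure
(for two classes the weighted TP rate equals the accuracy), MCC from the
standard covariance formula (denominator 0 → 0, flagged), accuracy =
trace/total.

By default standardization + PCA are refit inside each training fold and
applied to the held-out fold, which is leakage-safe. A `full_dataset_pca`
flag instead fits PCA once on the full table before splitting — the
protocol of full-dataset-PCA evaluation tools; the two give different
numbers and neither is asserted to be the historical one.

## Problem sizes and budgets

One case (1117 features) extracts in well under a minute on one CPU
(~0.6 s at the default grid). The power properties are measured as a
20-seed sweep of the full pipeline at the study-sized cohort (11 + 16),
the package's chosen problem size for a property that is statistical
rather than per-case. The determinism check reruns a reduced (3 + 3)
configuration and compares artifacts byte for byte.

## Known limitations

- The synthetic phenotypes differ only in texture correlation length;
  shape features carry no class signal by construction.
- The wavelet boundary is periodic and the LoG boundary reflective; near
  the grid edge the two derived-image families therefore make different
  extrapolation assumptions (the default ROI sits away from the edge).
- The χ² approximation to the Kruskal-Wallis null is used throughout; an
  exact permutation option is not implemented.
- No bias-field correction, histogram matching, DICOM interoperability or
  image registration: volumes and masks must arrive congruent.
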