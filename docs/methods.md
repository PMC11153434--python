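# Methods

This note documents what `conseg` models, the parameter choices that matter,
and what its synthetic experiments can and cannot say about clinical data.

## Phantom model

Each case is a single ellipsoidal tumor in a thoracic-like scene: a body
background at SUV 1.0, a surrounding low-uptake lung region at SUV 0.4
(an ellipsoidal halo 2.5 cm beyond the tumor), and the tumor itself.  The
grid defaults to 40 × 200 × 200 voxels of 0.50 × 0.41 × 0.41 cm³, the
in-plane matrix and voxel size of the PET acquisitions the suite emulates.

Intra-tumor heterogeneity is a core/rim profile plus a smoothed Gaussian
random field:

    uptake(x) = uptake_base · (1 + A · clip(0.5·(0.5 − r²(x)) + 0.8·g(x), ±1.5))

where r² is the normalized ellipsoidal radius, g is a seeded white-noise
field smoothed to a 0.6 cm correlation length and normalized to unit
standard deviation inside the tumor, and A = 0.15 by default.  With A = 0
the tumor is exactly flat at `uptake_base` — useful for degenerate-case
tests.  No texture law is claimed to be physiological; it only has to
produce heterogeneous uptake with a controllable amplitude.

The imaging chain is a Gaussian PSF (FWHM 6 mm, typical clinical PET
resolution) followed by scaled-Poisson noise: a voxel with blurred value *b*
is drawn as *s*·Poisson(*b*/*s*), so its mean is *b* and its variance *s·b*
— variance grows linearly in the noise scale *s*, which the tests verify
empirically.  Tomographic projection and reconstruction are deliberately
not modelled; the ground truth is the noise-free voxelized ellipsoid
(voxel centers inside the surface), so it is independent of any
segmentation choice.

### Suite conditions

The default suite is 13 cases.  Target volumes are spaced log-uniformly
over [3.8, 54.0] cm³ so that the voxelized ground-truth volumes stay inside
the 3.45–56.40 cm³ band the experiment emulates; random semi-axis ratios in
[0.85, 1.18] break sphericity.  `uptake_base` is drawn from [4.7, 5.9] and
the noise scale is 0.01 SUV; these two values were calibrated together,
once, so that the post-simulation SUVmax of the suite spans roughly
4.5–7.6 — matching the 4.58–7.87 range of the emulated experiment — and
were not revisited afterwards.  Every case derives its seeds from the
master seed, so the whole suite is a pure function of (config, seed).

### Initial masks

Two operator-style masks per case: *rectangular* is the ground-truth
bounding box dilated by 3 voxels; *irregular* is the ground truth dilated
by 2 voxels with a seeded smooth boundary perturbation (amplitude 1 voxel,
correlation 2 voxels), minus any configured hot-distractor region.  Both
contain the ground truth by construction.  The hot distractor (a nearby
high-uptake blob that irregular masks must exclude) is off in the default
suite and exercised in unit tests.

## Segmentation methods

All methods operate only inside the supplied initial mask and reduce their
output to one 26-connected component.

* **41MAX** — voxels ≥ 0.41 × (maximum inside the mask).
* **ST** — contrast-oriented threshold, iterated to a fixed point:
  T = a·mean{voxels ≥ 0.70 × current max} + b·BG, with BG the mean in a
  shell 2–4 voxels outside the current contour.  The (a, b) pair is a
  scanner calibration in the original method; without a scanner, the
  package ships a = b = 0.5 and exposes both.
* **AP** — affinity propagation (scikit-learn) on voxel intensities,
  negative squared distance similarity, median-similarity preference,
  damping 0.9 (lower damping rarely converges on near-duplicate 1-D data;
  non-convergence falls back to an Otsu split, flagged).  The clusters
  partition the intensity range; candidate thresholds are the boundaries
  between intensity-adjacent clusters and the one maximizing the two-class
  between-class variance is the cut.  The tumor is the largest connected
  grouping above the cut: an FDG-avid target is by definition hyperintense,
  so a background grouping is never an acceptable tumor contour — this
  mirrors the histogram-clustering lineage of AP-based PET delineation and
  the clinical-acceptability check an operator applies.  Above 1000 voxels
  a seeded subsample is clustered and labels propagate to remaining voxels
  by nearest intensity.
* **MASAC** — a two-region piecewise-constant active contour minimizing
  Σ_in (x−c₁)² + Σ_out (x−c₂)² + λ·perimeter by threshold dynamics
  (reassign by pointwise energy difference plus λ·(½ − smoothed indicator)),
  initialized from the 41MAX contour; λ = 3 by default.  This is a
  documented surrogate for the published active-contour method whose full
  internals are not reproduced here; it honours the λ = 3 operating point.

**ConSeg** fuses the four masks by voxel-wise majority vote.  The default
threshold for four voters is the strict majority 3; it is a configuration
knob because consensus literature also uses ≥ 50 % (2-of-4) rules.  An
empty consensus lowers the threshold one vote at a time, flagged.

## Feature catalog

107 features in seven classes (14 shape, 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM, 14 GLDM), with names and definitions following the
widely used public radiomics catalog (IBSI-aligned, including its
documented deviations, e.g. Kurtosis is not excess kurtosis and first-order
Energy is the raw sum of squares).  Intensities are discretized with a
fixed bin width of 0.25 SUV anchored at the ROI minimum:
label(x) = ⌊(x − min)/w⌋ + 1.  No resampling and no image filters are
applied.  Texture matrices are built in 3-D at distance 1 over the 13
unique directions of the 26-neighbourhood; GLCM (symmetrized) and GLRLM are
averaged over directions with equal weight, GLSZM/NGTDM/GLDM are
direction-free; voxels outside the ROI never contribute.  Formulas use the
actual gray-level values present in the ROI; the GLDM dependence criterion
is |Δlevel| ≤ α with α = 0.

Degenerate inputs are flagged, never silently zeroed: a single-voxel mask
yields valid shape-volume and first-order values with all texture features
marked invalid (no voxel pairs exist); a single-gray-level ROI invalidates
the correlation-type GLCM features (Correlation, MCC, Imc1, Imc2) while
Contrast etc. are computed as their closed-form limits.  Percentiles use
linear interpolation between order statistics; moment ratios of a constant
ROI are defined as 0.

Shape features come from a marching-cubes mesh (volume by the divergence
theorem, surface area from the triangles).  Note the mesh chamfers right
angles, so the mesh volume of a voxel cuboid sits a few percent below
width × height × depth — the behaviour of mesh-based catalogs, asserted in
the tests.  Axis lengths are 4·√eigenvalue of the physical voxel-center
covariance; maximum 2-D/3-D diameters are measured between surface-voxel
centers (convex hull accelerated), a voxel-center approximation to the
mesh-vertex definition.

## Reliability analysis

ICC(2,1) — two-way random effects, single measurement, absolute agreement —
is computed from the ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

Three designs: between the two initial masks for a fixed method (k = 2),
among the four individual methods for a fixed mask style (k = 4), and
segmentation versus ground truth (k = 2, synthetic suites only).  Categories
follow |ICC|: excellent ≥ 0.9, good [0.75, 0.9), moderate [0.5, 0.75),
poor < 0.5; the good/excellent boundary is implemented as [0.75, 0.9) so the
printed bands partition without gaps.  Negative ICCs (a small-sample
artefact) are kept and flagged in per-feature output but excluded from
category counts and medians, with the excluded fraction reported — this
retains auditability while matching the common practice of neglecting them.
Features invalid in any design cell are dropped pairwise and counted.  The
*stable set* is the features with ICC ≥ 0.75 in every requested design;
the acceptance script also reports the ≥ 0.9 subset.

## Correlation structure

Feature–feature Spearman matrices (average ranks for ties; constant columns
flagged NaN) are compared across settings.  The reference feature ordering
is the average-linkage hierarchical-clustering leaf order on distance
1 − |ρ| from the ConSeg/irregular matrix, reused to render other matrices.
The scalar similarity between two matrices is the Pearson correlation of
their upper triangles (undefined entries dropped pairwise); it makes the
qualitative claim "masks and methods barely move the correlation structure,
datasets do" testable as an ordering.

## Problem sizes and numerics

The shipped defaults are the package's study conditions: 13 cases on the
40 × 200 × 200 grid; a full pipeline run takes under a minute on one CPU.
Tests use a reduced 16 × 48 × 48 grid with 2–3 cases where only mechanics
are under test, and five seeded replicates of the full 13-case suite for
the reliability-ordering checks.  Convergence tolerances: ST stops on an
unchanged contour or |ΔT| < 1e-4; MASAC on an unchanged mask or a relative
energy change < 1e-4 (cap 100 sweeps).  Ties in connected-component size
resolve to the first label, making postprocessing deterministic and
idempotent.  All randomness flows from per-stage streams derived from one
master seed; reruns are bit-identical for masks and feature CSVs.

## What the synthetic suite does and does not show

The generator reproduces the *geometry and statistics* that drive contour
variability — heterogeneous uptake, PSF blur, count noise, loose operator
masks — so method orderings (consensus ≥ its weakest voter; irregular
masks ≥ rectangular; first-order Energy/Maximum among the most stable
features) are meaningful on it.  It does not model reconstruction
artefacts, scatter/attenuation, respiratory motion, multi-focal disease or
operator-drawn masks on real anatomy, so absolute ICC levels on clinical
data will generally be lower and dataset-specific.  Passing tests validate
the pipeline's internal correctness and the qualitative orderings under
the stated conditions, not clinical performance.

## Known limitations

* MASAC is a surrogate active-contour, not a reimplementation of the cited
  algorithm's internals.
* ST ships uncalibrated (a = b = 0.5); real deployments calibrate (a, b)
  per scanner.
* Maximum 2-D/3-D diameters use surface-voxel centers rather than mesh
  vertices (sub-voxel differences).
* The lung/body background is piecewise constant; no anatomy texture.
* Negative-ICC exclusion happens at the summary stage only; per-feature
  tables always carry the signed estimate.
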