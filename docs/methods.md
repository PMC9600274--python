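# Methods

## Data model and conventions

A lesion is three co-registered 3D grids on one voxel lattice: an ADC map
(10⁻³ mm²/s), a VE map (arbitrary enhancement units; the normalization of
portal-venous enhancement is scanner- and protocol-specific, so VE is
treated as a given scalar map), and a binary mask. Voxel indices are
0-based; all neighborhood offsets are expressed in voxel-index space.
Volumes must arrive pre-aligned: NIfTI orientation metadata is preserved
but never used to resample, and shape/spacing agreement is enforced at
load time (spacing tolerance 10⁻³ mm). Masks must be strictly {0, 1} with
at least one foreground voxel; every feature is computed over the masked
voxels only.

## Gray-level discretization

Matrix-based texture operators consume integer labels 1..Ng produced by
equal-width binning between the masked minimum m and maximum M:
label(v) = ⌊Ng(v−m)/(M−m)⌋+1, with v = M clipped into bin Ng and a
constant region (M = m) collapsing to label 1. Equal-width min–max
binning makes labels invariant to positive affine rescaling of the map
and is the convention of the classical texture toolboxes; it also nests:
bins at Ng = 16 are exact unions of bins at Ng = 256, so coarser labels
are a deterministic coarsening of finer ones. Supported Ng values are
{16, 32, 64, 128, 256} with 64 the default operating point. Histogram
moments (variance, skewness, non-excess kurtosis) are computed on the
quantized labels, matching the toolbox convention of grouping them with
texture features at a stated Ng.

## Texture families

- **GLCM** — distance-1 co-occurrences along the four in-plane directions
  (0°, 90°, 45°, 135°) of each axial slice, pooled over slices and
  directions before normalization (pooling counts is equivalent to
  averaging per-direction matrices when pair counts are equal, and
  remains well defined when they are not), symmetrized, normalized to
  sum 1. Pairs with an unmasked member are skipped. Features: contrast,
  correlation, energy, variance, sum average, dissimilarity,
  autocorrelation, entropy (log₂), homogeneity. The marginal mean μx
  equals μy by symmetry; correlation of a zero-variance matrix is
  defined 0.
- **GLRLM** — maximal same-label runs of consecutive masked voxels along
  the same four in-plane directions, per slice (runs never cross slices
  or unmasked voxels), pooled. The tiling identity
  Σⱼ j·R(i,j) = 4 × n_voxels is asserted on every build. The 13 classical
  emphasis/non-uniformity/variance features.
- **GLSZM** — zones are maximal 26-connected 3D components of equal
  label; zones partition the mask (asserted). The 13 size-zone analogues
  of the run-length set.
- **NGTDM** — 26-neighborhood (3×3×3 minus center); only masked
  neighbors contribute to the neighborhood mean, and voxels with no
  masked neighbor are excluded. The classical five (coarseness, contrast,
  busyness, complexity, strength), with ε = 10⁻⁶ capping the coarseness
  singularity of a uniform region (coarseness of a constant region is
  1/ε). Note the classical coarseness denominator sums deviations over
  voxels, so coarseness is region-size dependent: comparisons between
  textures are meaningful at fixed region size, and the test suite
  phrases its smoothness property accordingly.

In-plane (2D, per-slice) directions are used for GLCM/GLRLM because the
co-occurrence/run conventions adopted here are explicitly directional and
planar; GLSZM and NGTDM are fully 3D. A 13-direction 3D GLCM variant was
deliberately left out of scope.

## Global features

Masked mean/max/min of each map (6), plus three shape features: volume
(foreground count × voxel volume), surface area (spacing-weighted count
of exposed voxel faces — deterministic and oracle-checkable, unlike
meshing), and solidity. Solidity is the foreground voxel count over the
voxel count of the convex hull rasterized on the same lattice (hull of
voxel centers, no half-voxel dilation), which keeps it in (0, 1],
spacing-invariant, and ≈1 for convex digital shapes; the half-voxel
offset variant inflates the hull by a surface shell (~7% for a
desk-scale ellipsoid) and was rejected.

## Random forest and out-of-bag evaluation

Trees are Gini CART trees (scikit-learn) grown on bootstrap samples of
size n drawn with replacement; each split considers mtry random
predictors, and leaves below `min_leaf` samples are not split. Defaults
are 500 trees, min_leaf 9, mtry 44 —
clipped to min(44, p), the only interpretation that runs for the
2-predictor baseline. One master seed drives per-tree bootstraps and
split sampling through a stable stream-splitting scheme
(`SeedSequence(seed, spawn_key=(tree,))`), so runs are exactly
reproducible; predictor columns are sorted by name internally, making
metrics invariant to the column order of the design table.

OOB class probabilities for sample k average only trees where k was out
of bag; samples never out of bag (probability (1−1/n)^(n·T), negligible
at 500 trees) are flagged and excluded. Classification is argmax with
ties to the lowest class index (well < moderate < poor; the two-class
task merges moderate+poor). The error-vs-trees curve accumulates
predictions in growth order; its final point equals the scalar OOB error.

AUC is the Mann–Whitney rank statistic of the OOB "well" probability
against the well-vs-rest indicator (in the multi-class model the "well"
probability column is used directly), with a DeLong variance for the 95%
CI. Model comparison: two-sided DeLong test for correlated ROC curves on
the shared OOB scores, and a chi-square test (no continuity correction)
on the 2×2 model × correct/incorrect table treating the two models'
outcomes as independent columns; the paired McNemar alternative is
available behind a flag and is statistically preferable, but the
independent-columns form is the primary contract here.

Variable importance is minimal depth: per tree, the depth of the
shallowest node splitting on a predictor (the root of its maximal
subtree, root = 0); predictors unused in a tree are assigned that tree's
height + 1 — a simple, monotone convention chosen over the
distribution-based imputation of the minimal-depth literature. The
forest-level importance is the mean over trees, ranked ascending.

## Synthetic phantom cohorts

The generator emulates the input contract and the statistical structure
the analysis assumes, not MR physics. Per lesion: a mask (random
ellipsoid, semi-axes uniform in 6–14 mm, optionally perturbed by a
smooth boundary deformation of relative amplitude 0.15, reduced to its
largest 26-connected component, ≥27 voxels guaranteed) on a 48×48×32
grid at 1.5×1.5×3 mm — desk-scale and deliberately anisotropic. Each map
is

    class_mean + δ + field_sd·(G − Ḡ_mask) + noise_sd·ε

where G is white noise smoothed by a Gaussian kernel of physical scale
equal to the grade's correlation length and rescaled to unit marginal
variance, δ ~ N(0, lesion_mean_sd²) is a per-lesion offset drawn
identically for every grade, and ε is voxel noise. Centering G to zero
mask-mean makes the masked mean carry only class_mean + δ: the mean
signal and the texture signal are controlled independently, so with
equal class means a mean-only classifier is uninformative *by
construction* (without centering, the correlation length leaks into the
dispersion of the lesion mean and a mean-only forest reaches AUC ≈ 0.84
on nominally "texture-only" cohorts).

Defaults (chosen once, before the acceptance suite was run): ADC class
means 1.30/1.10/0.90 ×10⁻³ mm²/s (well > moderate > poor, within the
range reported for HCC); VE means 1.40/1.15/0.90 in normalized arbitrary
units of order one so a single field_sd (0.25) and noise_sd (0.05) serve
both maps; correlation lengths 6/3/1.5 mm (poorer differentiation =
rougher texture); lesion_mean_sd 0.25, comparable to the 0.20 class
separation, reflecting the large between-lesion overlap of mean ADC
across grades in real cohorts — this puts the mean-only baseline at a
multi-class OOB error around 0.4 rather than at saturation. Two regimes
are pre-registered: `mean+texture` (defaults as above) and
`texture-only` (class means equalized).

What the phantoms do **not** model: MR acquisition physics, b-value
fitting, contrast kinetics, multi-lesion-per-patient correlation,
scanner harmonization, segmentation error. Passing tests therefore show
that the pipeline recovers the kinds of signal it claims to measure
under controlled conditions — not that any particular clinical accuracy
transfers to patient data.

One interaction worth knowing: at long correlation lengths the
within-mask standard deviation of the field shrinks (a 6 mm field in a
~10 mm mask is nearly a constant plus gradient), so fixed-amplitude
voxel noise increasingly dominates label-scale differences and
co-occurrence contrast is no longer monotone in correlation length
beyond ~3 mm. The texture-response test disables voxel noise to isolate
the field response; the classifier, which uses many families at once, is
unaffected.

## Problem sizes and numerical choices

The test suite runs cohorts of 3–60 lesions per grade; the regime
recovery checks use 57/grade (171 lesions, a realistic clinical cohort
scale) over 10 master seeds, and the acceptance script one seed per
regime — sizes chosen so the whole suite completes in minutes on one
CPU. Oracle equivalence is asserted to 10⁻¹⁰ on exhaustive 3×3×1 and
100 random masked 5×5×3 grids against naive loop implementations.
Degenerate inputs have defined values: constant regions yield label 1,
zero histogram moments (skewness/kurtosis defined 0 at zero variance),
GLCM energy/homogeneity 1 and entropy/contrast 0, NGTDM
contrast/busyness/complexity 0. Matrices that cannot be formed (no
adjacent masked pair; no voxel with a masked neighbor) raise a
degenerate-matrix error carrying the lesion and family.

## Known limitations

- GLRLM runs are per-slice by construction; whether runs should merge
  across slices is a convention choice, fixed here as planar.
- The chi-square model comparison ignores the pairing of OOB outcomes
  (use `paired_chi=True` for McNemar).
- OOB AUC of noise-only models is mildly biased below 0.5 (a known
  artifact of bagged OOB scores); the null-calibration tests use 3-SE
  bands that absorb it.
- Feature values are not harmonized across scanners or protocols;
  applying the pipeline to heterogeneous real cohorts would require an
  intensity-standardization step that is out of scope.
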