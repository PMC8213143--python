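# Methods

## Problem setting

Radiomic texture indices (TIs) computed from grey-level matrices are
sensitive to the grey-level discretization applied to the image before the
matrices are built. This package implements and compares the three
discretization conventions in use for MRI texture analysis, together with
the downstream analyses that reveal their practical consequences: how TI
values drift with the binning parameter, how strongly TIs correlate with
lesion volume, and how many TIs separate pathological from healthy tissue.

## Discretization schemes

For voxel intensities `I(i)` inside a VOI:

* **LAR** (lesion absolute resampling; fixed bin size anchored at the VOI
  minimum): `I_LAR(i) = floor(I(i)/B) - floor(I_min/B) + 1`. The smallest
  level is exactly 1.
* **AR** (absolute resampling; fixed bin size anchored at absolute zero):
  `I_AR(i) = ceil(I(i)/B) - 1`. Levels are independent of the VOI minimum,
  so the same intensity always maps to the same bin in every lesion.
  Because the raw equation can yield level 0, a +1 shift is applied at
  matrix-construction time; the shift preserves every level difference and
  the shifted value is what intensity-weighted features use.
* **LRR** (lesion relative resampling; fixed bin number):
  `I_LRR(i) = 1` if `I(i) = I_min`, else
  `ceil(D * (I(i)-I_min) / (I_max-I_min))`, mapping the VOI range onto
  `{1..D}` with the extremes pinned to 1 and D. LRR is invariant under any
  positive affine intensity map.

Bin parameters are swept over `B = {1, 5, 10, ..., 100}` (21 values) and
`D = {8, 16, 32, 64, 128, 256, 512, 1024}` (8 values); `B = 50` and
`D = 64` are the headline settings used for the statistical comparisons.

**Percentile clipping.** For the fixed-bin-size schemes, intensities are
first winsorized to the VOI's 10th–90th percentile (linear-interpolation
percentile definition, pinned for reproducibility). Winsorization retains
every voxel at the bound rather than excluding it, because the texture
matrices need the intact voxel lattice. LRR uses the raw VOI minimum and
maximum by default; clipping for LRR can be enabled through the scheme
config. No image normalization is applied anywhere, deliberately: the
interaction between unnormalised arbitrary-unit MR intensities and the
discretization scheme is the object of study.

A subtlety worth recording: AR and LAR level arrays differ by the constant
`floor(I_min/B)` whenever no intensity falls exactly on a bin edge (because
`ceil(x) = floor(x) + 1` off integers). Level-translation-invariant
features (Contrast, Dissim, the entropies) then agree between AR and LAR to
floating-point accuracy. An intensity exactly at a multiple of `B` breaks
the correspondence, since the ceil and floor conventions assign the edge
voxel to different bins; for continuous data this is a measure-zero event.

## Texture matrices and features

All matrices are built in 3D from the masked voxels only:

* **GLCM**: ordered neighbor pairs at Chebyshev distance 1 along the 13
  unique 3D directions, both orderings counted (symmetric), merged into a
  single matrix and normalised. Pairs with either voxel outside the mask
  are skipped.
* **GLRLM**: maximal same-level runs along each of the 13 directions,
  truncated at the mask boundary, merged. Every masked voxel belongs to
  exactly one run per direction, giving the partition identity
  `sum(length x count) = 13 x n_voxels` used as a test invariant. The run
  percentage uses the merged denominator `13 x n_voxels`.
* **GLSZM**: 26-connected components of constant level (8-connected in the
  2D grids used by tests), `sum(size x count) = n_voxels`.

The grey-level axis runs `1..Ng` with `Ng` the maximum observed level, and
unobserved intermediate levels are kept as empty rows: the
intensity-weighted features use the level *value*, which is precisely what
distinguishes absolute from relative binning semantics.

The 40-feature roster is 18 GLCM + 11 GLRLM + 11 GLSZM indices evaluated
with the standard reference formulas (entropies in bits). Merging matrices
over directions (rather than averaging per-direction features) is pinned;
per-direction averaging would be a config-level extension.

**Degenerate inputs.** A VOI with a single observed grey level would
produce NaNs in a few formulas. Defined fallbacks are used instead so large
synthetic sweeps cannot poison the statistics stage: entropies 0, GLCM
Correlation 0 (zero marginal variance), NormInvDiff 1. A single-voxel VOI
has no neighbor pairs and is rejected outright; the pipeline logs and
excludes such VOIs with a reason.

## Synthetic phantom cohort

The generator emulates the statistical structure the analysis needs, not MR
physics. Each subject consists of:

* a background stationary Gaussian random field (white noise convolved with
  an isotropic Gaussian of width `correlation_length` mm, then empirically
  standardised to the target mean/sd) — defaults 600 ± 60 arbitrary units,
  correlation length 1.5 mm;
* 1–3 ellipsoidal lesions (group-dependent) whose interior is an
  independent field with group- and contrast-specific presets (e.g. stroke
  T1-hypointense 420 ± 85, enhancing tumor T1-hyperintense 1080 ± 150);
* a global Gaussian blur (sigma 0.5 mm) emulating partial-volume mixing at
  the lesion boundary;
* a per-subject multiplicative gain drawn from U(0.8, 1.2) that scales all
  means and sds, emulating the arbitrary-unit scale variability of
  unnormalised MR acquisitions;
* a clamp at 1.0 intensity unit guaranteeing the strictly positive inputs
  the AR equation requires.

The intensity scale was chosen so the fixed-bin-size grid `B = 1..100`
spans fine-to-coarse binning relative to a VOI's clipped intensity spread
(roughly 120–460 units), the regime the grid presumes for clinical data; at
a much narrower scale the coarse half of the grid would degenerate to one
or two occupied bins whose occupancy depends on bin alignment rather than
on texture.

Lesion geometry is shared across the two contrasts of a subject
(co-registration), confined to one hemisphere with clearance so that every
lesion's mirror image across the midsagittal plane — the co-lateral control
position — fits inside the grid and no lesion, control, or dilated manual
VOI overlaps another. Subject seeds derive from the master seed, the group
label and the within-group index via a splitmix64 mix, so resizing or
removing one group never perturbs the other subjects' realisations.

What the phantom does *not* model: MR physics (TR/TE, coils, bias fields),
anatomy, spatial resolution effects, registration error, disease-specific
lesion morphology. Cohort-level findings on synthetic data are therefore
structural/qualitative reproductions, not quantitative predictions for any
real cohort.

## VOI construction

Two segmentation styles per lesion:

* **elliptical**: an axis-aligned ellipsoid at the lesion center with
  semi-axes shrunk by the partial-volume blur width (default: the blur
  sigma), sampling the lesion core only;
* **manual-like**: the true lesion mask dilated by a ball of radius 2 mm
  (configurable), so mixed boundary voxels are included, as with hand-drawn
  contours.

Controls are voxel-count-preserving reflections across the midsagittal
plane. A (lesion, style) pair enters the analysis only if the pathological
VOI reaches 1 cm^3; its control is kept or dropped with it. Voxel
membership is decided by the voxel center, and world coordinates are
`index x spacing` (0-based).

## Statistics

* **Spearman feature-volume correlation** per (feature, group, role,
  contrast) cell with average-rank ties, reported as rho and R^2 = rho^2;
  `R^2 > 0.5` (|R| > 0.71) flags high correlation. Cells with a constant
  feature or volume are flagged degenerate and emitted as missing, never as
  zero. The full design at one (method-param, segmentation) is a 40 x 12
  map (3 groups x 2 roles x 2 contrasts) = 480 analyses.
* **Wilcoxon rank-sum screening** of pathological vs control values per
  (feature, group, contrast): exact enumeration when the pooled tie-free
  sample has at most 10 observations, otherwise the normal approximation
  with tie and continuity corrections. Significance counting uses strict
  p < 0.05 with no multiple-testing correction — deliberately liberal, to
  mirror common screening practice; counts are comparisons across
  conditions, not confirmatory inferences.
* The observation unit is the lesion, not the patient; all lesions of
  multi-lesion subjects enter the analysis.

## Calibration experiments and their design

* **Type-I error.** On null cohorts whose "lesions" share the background
  texture, the rank-sum screening should reject at its nominal rate. The
  binomial reference bounds assume independent tests, so the experiment
  performs one test per independently generated cohort (240 replicates of
  12 + 12 VOIs, rotating through the 40-feature roster) rather than pooling
  the 40 strongly correlated per-cohort tests. Lesion geometry and the
  per-subject gain are held fixed in the null: VOI size and gain are shared
  covariates of a subject's two VOIs, and letting them vary correlates the
  arms, making the unpaired test conservative rather than nominal — a
  caveat that applies equally to volume-matched control designs on real
  data.
* **Volume-independence null.** With lesion texture independent of lesion
  size by construction, pooled Spearman feature-volume p-values of the GLCM
  family under AR are close to uniform (Kolmogorov distance < 0.1 over
  ~1000 pooled tests). The run-length and size-zone families are excluded
  from this null on purpose: indices aggregating raw run/zone counts are
  intrinsically sample-size-dependent and therefore volume-correlated by
  construction — which is exactly the bias the R^2 maps expose.
* **Binning stability.** On one fixed textured VOI, the coefficient of
  variation across the full D grid separates binning-robust indices (GLCM
  Correlation, NormInvDiff; CoV ratios >= 10x smaller than JEntropy's)
  from binning-driven ones.
* **Monotone binning response.** Joint entropy rises with bin number under
  LRR and falls with bin width under AR on averages over 48 replicate VOIs
  that rotate through the disease presets. Averaging over varying intensity
  locations matters: for a single fixed intensity location the response at
  coarse B is governed by the alignment of the absolute bin grid with the
  VOI range and is not monotone.
* **Discrimination study.** At B=50/D=64 on a cohort with genuine
  lesion/background texture contrast (6 subjects per group), significant-TI
  counts are tabulated per (method, segmentation) out of 240 tests each,
  and high-volume-correlation cells per method. The expected directional
  patterns (AR >= LRR significant TIs; elliptical >= manual; LRR inflating
  volume correlation) are reported and logged as soft expectations, not
  asserted: they are cohort-level tendencies whose strength depends on the
  synthetic presets.

## Problem sizes and numerics

Default study runs use the reduced grids B in {10, 50, 100}, D in
{8, 64, 256} with 6 subjects per group on a 64^3 1 mm grid;
`StudyConfig.full_scale()` selects the complete 21 + 8 grid sweep with the
22/22/27 cohort. Brute-force oracle comparisons use >= 100 random masked
grids up to 4^3 voxels at 1e-12 relative tolerance. All randomness flows
from explicit integer seeds through splitmix64-derived substreams; repeated
runs are byte-identical, and LRR levels guard the top bin against float
roundoff with a final clip.

## Known limitations

* The phantom's texture presets are free parameters; none of the paper-like
  cohort numbers produced here should be read as estimates for real data.
* Manual-like segmentation is a dilation, not a model of inter-rater
  variability.
* The rank-sum screening inherits the conservatism described above whenever
  VOI pairs share covariates (size, gain); cohort significance counts are
  therefore comparable across conditions but not calibrated p-value
  inventories.
* First-order histogram, shape, and neighborhood grey-tone features are out
  of scope, as are intensity normalization strategies and DICOM ingestion.
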