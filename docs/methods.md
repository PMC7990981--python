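# Methods

## Problem and approach

Semi-quantitative analysis of brain ¹⁸FDG PET requires dividing each
subject's image by the uptake of a reference region (SUVr), because raw
voxel intensities carry a subject-specific multiplicative nuisance
(injected dose, scanner sensitivity, uptake time). A good reference region
is one whose own metabolism is stable with respect to the effect under
study — here, healthy ageing, which is known to depress glucose metabolism
in almost all grey-matter regions. `petref` implements an exhaustive,
data-driven selection procedure and the voxelwise analysis that validates
it:

1. **Exhaustive normalization grid.** For each of the R candidate
   reference regions, convert the subjects × regions uptake matrix to SUVr
   and compute the Pearson correlation of every target region's SUVr with
   age. This yields an R × R grid of coefficients.
2. **Median-based scoring.** Score each reference by the *median* of its
   row of coefficients. Because ageing depresses nearly every region, a
   truly age-stable reference makes most targets correlate negatively with
   age, driving the median down; an age-declining reference cancels the
   common trend and pulls the median toward zero or positive values. The
   selection rule flags references with median r strictly below −0.5.
3. **Structure grouping.** Flagged fine regions are pooled into anatomical
   structures (cerebellum lobules and vermis subdivisions → "cerebellum";
   "Pons" → "pons"; all other regions are their own structure), matching
   how a reference would be used in practice.
4. **Voxelwise validation.** For competing normalizations, a mass-univariate
   GLM (intercept + age + sex) tests voxelwise metabolic decline with age;
   the total significant cluster volume (mm³) measures each
   normalization's sensitivity.

The published 120-region coefficient table for two healthy-control
databases (a conventional-camera cohort, n = 56, and a digital-camera
cohort, n = 78) is packaged as a TSV fixture; applying the selection rule
to it reproduces the published finding that the cerebellum and the pons
are the only structures with median coefficients below −0.5, and the
fold-ratio arithmetic on the published cluster volumes reproduces the
1.7-/2.5-fold advantage of pons normalization.

## Statistical details

**Pearson grid.** Plain product-moment correlation; sex is not partialled
out at this stage (it enters only the voxelwise model). The self-normalized
reference column is the constant 1, so its correlation is undefined; the
grid marks it (and any other numerically constant column, relative
peak-to-peak ≤ 1e−9) as NaN and summaries exclude rather than impute such
entries. The per-reference summary reports the median (average-of-two for
even counts) and the *strongest* coefficient, read as the minimum signed
value (most negative), not max |r| — the published table contains a row
(Caudate_R) whose "strongest" 0.307 is below its median 0.497, which is
impossible under a max-|r| reading but consistent with the signed minimum.

**Selection.** Strict inequality at the threshold: median exactly −0.5 is
not selected. Ranking is by ascending median with lexicographic name
tie-breaks, so results are total orders and byte-reproducible.

**Voxelwise GLM.** Ordinary least squares per voxel on the design
(1, age, sex), sex coded 0 = man / 1 = woman. Decline is tested one-sided
through the contrast c = (0, −1, 0), so positive t means loss of uptake
per year. Degenerate voxels: an exact fit (residual sum of squares at
numerical-noise level, ≤ 1e−12 of the data sum of squares) with a nonzero
contrast estimate maps to ±∞ by the estimate's sign; 0/0 maps to t = 0 and
never clusters. A contrast estimate below 1e−10 of the voxel's coefficient
norm counts as zero, so constant data do not produce spurious infinities.

**Family-wise error.** Instead of random-field theory, the critical t is
the empirical (1 − α) quantile (upper interpolation) of a maxT permutation
null: the age column is permuted across subjects (each subject keeps their
sex), the model is refit, and the maximum in-mask t is recorded per
permutation. This is exactly specifiable and its calibration is testable:
under a global-null simulation the measured family-wise rejection rate at
α = 0.05 falls in the nominal band. Analysing a second cohort "at the same
T level" as the first is supported by passing a fixed threshold
(`fixed_t`) instead of recomputing the quantile.

**Clusters.** Supra-threshold voxels ({t ≥ T}, infinities included) are
grouped by 26-connectivity (the SPM-style default; 6 and 18 available),
reported as voxel counts, counts × voxel volume in mm³, peak t and peak
index (ties broken by lowest linear index), sorted by descending volume.

## Synthetic cohort generator

There is no public raw-image dataset for this analysis, so validation runs
on synthetic cohorts that emulate exactly the statistical structure the
method exploits:

- **Regional means**: m_ik = b_k (1 + s_k (age_i − a0)) g_i + ε_ik, with
  baselines b_k ~ U(80, 120) arbitrary uptake units, fractional slopes
  s_k ~ U(−0.007, −0.002) per year (0.2–0.7% annual loss, the order of
  magnitude reported for grey-matter metabolic decline), a planted
  age-invariant region (slope 0, named "Pons" in the toy atlas), a
  per-subject global factor g_i ~ lognormal(0, 0.2) (≈20% dose/sensitivity
  spread), and additive noise ε_ik ~ N(0, 0.05·b_k).
- **Demographics**: two presets mirroring the control databases behind the
  packaged coefficient table —
  conventional: n = 56, age 50 ± 17 truncated to [21, 78], 33 women, 8 mm
  FWHM post-smoothing; digital: n = 78, age 58 ± 16 truncated to [22, 87],
  42 women, 4 mm FWHM. Ages are rejection-sampled (exact truncation); the
  woman count is exact, positions shuffled. Sex has no simulated metabolic
  effect by default: the analysis treats it purely as a nuisance covariate.
- **Volumes**: regional means painted into a procedural toy atlas (an
  ellipsoidal brain mask partitioned by nearest-centroid growth from
  seeded voxels; default 32×40×32 grid at 4 mm voxels, 12 regions), plus
  voxel noise at half the regional noise scale, then Gaussian smoothing at
  the preset FWHM (σ = FWHM/(2√(2 ln 2))/voxel size per axis, zero-padded
  boundaries) with the background re-masked to zero.
- **reference_age** defaults to the cohort age mean; centering affects
  baselines only, never correlations.

What the generator does *not* emulate: PET physics (attenuation, scatter,
partial-volume effects beyond Gaussian blur), anatomical geometry, spatial
normalization error, or nonlinear age trajectories. Passing tests
therefore show that the pipeline recovers a planted age-stable reference
and ranks normalizations correctly *given* the linear decline +
multiplicative nuisance model — they do not certify performance on real
scans with registration error or pathology.

## Validation suite and problem sizes

- Grid correctness: the vectorized grid equals a naive
  normalize-then-correlate double loop to 1e−12 on random 10-subject ×
  6-region matrices, and is invariant (1e−12) to per-subject rescaling of
  raw rows — the property that makes proportional scaling meaningful.
- GLM correctness: t-maps match per-voxel normal-equations solutions to
  1e−10 over every in-mask voxel of a full-size (32×40×32, n = 78)
  synthetic cohort.
- FWE calibration: 200 global-null cohorts (n = 30 on a 16³ toy grid),
  500 permutations each; family-wise rejection rate at α = 0.05 must land
  in [0.03, 0.07].
- Parameter recovery: over 20 seeded digital-preset cohorts, the planted
  age-invariant region's structure must top the median-r ranking in ≥ 18;
  and total significant volume under pons normalization must exceed the
  whole-grey-matter result in ≥ 18 (the qualitative headline). These runs
  use 200 permutations per threshold.
- `scripts/acceptance.py` recomputes the fixture-derived quantities and
  runs 10 synthetic seeds plus a 100-replicate calibration (300
  permutations each), completing in about a minute.

## Design choices on genuinely open points

- **Whole grey matter** is modelled as the union of all atlas regions
  excluding the brainstem-named ones (Midbrain, Pons, Medulla); the
  original grey-matter mask is not public, and proportional scaling by a
  global mean is the intent of that 120th "region".
- Whether the original analysis included the self-normalized region among
  its per-reference coefficients is not documented; this implementation
  excludes the undefined diagonal from medians, which cannot flip any
  selection decision at the published precision.
- The "two sole regions" statement is reproduced at structure level
  (region-level, six digital rows pass the threshold); per-system and
  pooled structure counts are both reported.
- A TSV lookup without a structure column loads with identity grouping
  (each region its own structure); the cerebellum/vermis/pons prefix rules
  are applied when building toy atlases and when grouping published region
  names.

## Known limitations

- The toy atlas is convex and has no hemispheric or laminar anatomy;
  structure grouping is exercised through three renamed regions only.
- The permutation null permutes the age column directly (sex kept attached
  to its subject); with strongly age-confounded sex distributions a
  Freedman–Lane residual scheme would be preferable.
- Printed coefficients are reproduced from the packaged table, not
  re-derived from raw scans (the underlying images are not public).
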