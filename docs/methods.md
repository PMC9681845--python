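# Methods

## Scope and model

`voitex` implements a volumetric texture-analysis pipeline for T2-weighted
MRI lesions, built around the gray-level co-occurrence matrix (GLCM) of a
manually segmented volume of interest (VOI). The chain is:

1. **Quantization.** VOI intensities are linearly binned to `Ng` gray
   levels (default 128) between the VOI's own minimum and maximum:
   `level = floor((x - min)/(max - min) * Ng) + 1`, clamped to `[1, Ng]`;
   a constant VOI maps entirely to level 1. Per-VOI min–max binning is used
   because MRI intensities carry no absolute calibration.
2. **Isotropic 3-D GLCM.** For each distance `d` in 1–5 voxels, level pairs
   at offset `d·u` are counted for all 13 unique direction generators `u`
   of the 26-neighborhood (one per antipodal pair: 3 axes, 6 face
   diagonals, 4 body diagonals), pooled into a single symmetric matrix per
   distance and normalized to sum to one. Diagonal offsets scale as `d·u`
   (Chebyshev distance), offsets live in voxel index space (anisotropic
   spacing is metadata only), and pairs with either endpoint outside the
   mask are skipped. A VOI admitting no pair at some distance yields an
   all-zero matrix flagged degenerate — recorded as data, not raised.
3. **Haralick parameters.** Eleven statistics per matrix: uniformity
   (angular second moment), contrast, correlation, variance (sum of
   squares), homogeneity (inverse difference moment), entropy, sum
   average, sum entropy, sum variance, entropy of difference, variance of
   difference. Formulas are in `voitex.haralick`'s module docstring; all
   entropies use `0·log 0 = 0`.
4. **Redundancy reduction.** (a) Each parameter's five distance columns
   are Spearman-correlated across subjects; when all pairs reach
   `|ρ| ≥ 0.9` the columns carry the same subject ordering, and the table
   collapses to the intermediate distance (q3 of five); parameters falling
   short are flagged but the collapse is not blocked. (b) At the reference
   distance, parameters are screened for mutual redundancy at
   `|ρ| ≥ 0.9` (the conventional "very strong" boundary; configurable).
5. **Group comparison.** Per retained parameter, a two-sided Mann–Whitney
   U test between the two groups, with per-group n, mean, SD, and median
   (the position measure reported alongside the mean). Raw p-values are
   reported by default (a Holm step-down adjustment sits behind a flag),
   with significance flags at α = 0.05.

## Design choices

**Log base.** Entropies default to natural log, switchable to base 2 or
10 (`log_base`). Published GLCM work is split on the convention, and the
choice rescales all three entropy statistics by a constant, which leaves
ranks — and hence the entire reduction and comparison stage — unchanged.

**Sum variance centering.** Sum variance is the central second moment of
the sum distribution, centered on the sum average. A well-known misprint
in the original formula list centers it on sum entropy instead; the
central-moment form is what the name "variance" means.

**Correlation at zero marginal variance** is defined as 0 rather than
missing so downstream tables stay rectangular; the degenerate flag records
the case.

**Exact versus asymptotic Mann–Whitney.** With `n1 + n2 ≤ 20` and no ties
the p-value comes from the exact null distribution of U; otherwise from a
mid-rank, tie-corrected normal approximation without continuity
correction (so exchangeable samples give p = 1). The method used is
recorded per comparison. Note the exact test is discrete: at group sizes
8 and 10 its attainable size at nominal α = 0.05 is 0.0434, which is the
rejection rate a correctly calibrated null simulation should show.

**Redundancy representative selection.** When parameters are very
strongly rank-correlated, one must decide which member of a redundant
cluster to keep. Statistics of the derived sum/difference marginals carry
no information beyond the joint distribution they are computed from — for
a symmetric GLCM, sum variance equals `2·variance·(1 + correlation)`
exactly, and the sum/difference entropies are bounded above by the joint
entropy. The elimination therefore considers the joint-distribution
parameters (contrast, correlation, entropy, homogeneity, uniformity,
variance) for retention first, each group in descending order of
centrality (mean `|ρ|` to the other parameters), and excludes a parameter
exactly when the data show `|ρ| ≥ threshold` against an already-decided
parameter (retained, or excluded and hence represented by its own retained
partner — redundancy is transitive). The procedure is deterministic,
idempotent on the retained set, excludes nothing when all correlations
are below threshold, and records the strongest partner and ρ for every
exclusion. A purely centrality-based choice was rejected after
measurement: near-deterministic derived statistics differ from their base
parameter by rank-correlation margins of ~0.01–0.03 at n = 18, well below
sampling noise, so any rule that compares the two members' correlation
profiles decides essentially at random.

## The phantom generator

No public dataset exists for the study design this pipeline addresses
(two odontogenic lesion classes, 8 + 10 subjects), so `voitex.synthetic`
generates seeded lesion phantoms with the statistical structure the
analysis assumes: a 48×48×24 grid at 0.79 × 1.15 × 4.00 mm spacing, an
ellipsoidal VOI (default semi-axes 15×13×8 voxels, jittered), and two
texture classes.

Each lesion combines four mechanisms, each targeting a distinct slice of
the feature vector:

- **Smoothed Gaussian field** (granularity σ = 1.6 voxels): the base
  texture; drives the correlation parameter.
- **Monotone histogram transform** `u ↦ Φ(z/τ)^γ`: the power tilt γ sets
  where the intensity bulk sits after min–max quantization and is the sum
  average axis (γ < 1 pushes mass toward high levels). The heterogeneous
  (AB-like) class uses γ = 0.76, the homogeneous (OKC-like) class γ = 1.0,
  so AB-like lesions have the higher sum average. The midrange
  compression τ is available but defaults to 1.
- **Posterization** (rounding the rim to P discrete intensity plateaus,
  AB-like 80, OKC-like 30): a tissue-homogeneity analogue that strongly
  lowers texture entropy while leaving the histogram's mean and spread —
  and hence sum average, variance and contrast — nearly unchanged. This is
  the entropy axis; AB-like lesions are effectively continuous and have
  the higher entropy.
- **Speckle decorrelation** (randomly permuting a fraction f of VOI
  voxel values; AB-like 0.20, OKC-like 0.08): thermal-noise analogue that
  preserves the marginal histogram exactly while destroying local spatial
  correlation; drives contrast up and the correlation parameter down.
- **Near-constant inner core** (a concentric ellipsoid at a jittered
  quantile of the rim intensities, 6–13% of the volume, spanning only a
  few gray levels): a fluid-pocket analogue that gives uniformity and
  homogeneity a variation axis of their own.

Per-subject jitter (lognormal on granularity, γ, noise, speckle and
posterization; uniform on lesion size, core fraction, quantile and core
width) makes within-class variance nonzero so the group comparison is
nontrivial. Background voxels outside the mask are generated but never
analysed — mask-respect tests depend on this. All randomness derives from
a master seed; per-subject seeds are recorded in the cohort manifest.

With these defaults the two classes separate on entropy and sum average
at q3 (two-sided exact Mann–Whitney p < 0.05 in ≈100% of seeded cohorts),
with AB-like higher on both, matching the ordering the pipeline is meant
to detect.

**What the generator does not emulate:** MR physics (no TR/TE/coil
modelling), anatomy beyond an ellipsoid, partial-volume effects at the
lesion boundary, inter-rater segmentation variability, or scanner drift.
Passing tests therefore demonstrate the pipeline's correctness and
calibration on fields with controlled texture structure, not clinical
performance.

## Known limitations

- **Exact reproduction of the redundancy-exclusion set is seed-dependent.**
  On default cohorts the excluded set is always a subset of {sum variance,
  sum entropy, variance of difference, entropy of difference} — the
  elimination never discards a primary parameter — but all four are
  excluded together only when four Spearman edges simultaneously clear the
  0.9 cutoff, which at n = 18 (per-edge sampling SD ≈ 0.05–0.08) happens
  in roughly a third of cohorts. Tightening all four edge means further
  while keeping the retained parameters mutually below 0.9 was not
  achievable in this phantom family: any mechanism that shares marginal
  spread between sum variance and variance also couples contrast to
  variance, and the posterization axis that ties the entropy family
  together also pulls uniformity toward entropy. A single 18-subject
  cohort that does show all four exclusions is entirely consistent with
  this distribution.
- At 128 levels and typical VOI sizes (≈10³–10⁴ voxels) the empirical
  joint entropy of a spread-out GLCM saturates near the log of the pair
  count, compressing entropy differences between very heterogeneous
  textures.
- Between-distance rank correlations below 0.9 are common for some
  parameters on the default phantoms; step 1 flags them (as the report
  records) without blocking the collapse to q3.

## Problem sizes used in the test suite

Repeated-cohort calibrations run on a reduced 24×24×12 phantom grid
(semi-axes 8×7×5): the null-calibration property is label exchangeability,
which does not depend on lesion size. The null suite uses 1000 cohorts,
the power check 100, and the reduction-reproduction check 10 master
seeds; `scripts/acceptance.py` uses 300, 50 and 10 respectively.
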