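# Methods notes

This note records the modelling assumptions, numerical conventions and
open design choices behind `radsubtype`, at the level of detail a
maintainer or reviewer needs to judge what the package's tests do and
do not establish.

## Enhancement maps

The series is assumed registered and bias-corrected upstream; the
package validates only grid compatibility (shape and spacing). Maps
are computed on the native grid and resampled afterwards like any
other intensity channel.

Degenerate voxels are a policy decision, not a formula consequence:
where `I_pre ≤ ε` (default 1e−6) the PE and SER are set to 0 and the
voxel is excluded from the map's validity mask; likewise for SER when
`|I_map − I_pre| ≤ ε`. SER is additionally clipped to `[0, 10]`
(configurable): near-zero denominators otherwise produce heavy tails
that would dominate the μ±3σ remap and the gray-level binning. No
NaN/Inf ever leaves the module.

Threshold segmentation keeps the largest 26-connected component of
`subtraction > threshold` above a minimum size; an empty result is
returned flagged rather than raised, so batch runs can report it.

## Image preparation

* Resampling: cubic B-spline for intensities, nearest neighbour for
  masks, to 1 mm isotropic. The output grid covers the input's
  physical extent without extrapolation; input already on the target
  spacing is passed through unchanged. B-spline order 3 is the
  conventional default.
* Normalization: μ and σ are the mean and population SD of gray
  levels **within the VOI**; the whole volume is clipped to
  `[μ−3σ, μ+3σ]` and affinely mapped to `[0, 100]`. All four channels
  (image + 3 maps) are normalized identically so their texture is
  comparable despite wildly different native scales; the parameters
  are returned so either convention can be reproduced. A constant VOI
  maps to the range midpoint. Normalizing twice is an affine map at
  most, so discretized levels — what texture analysis consumes — are
  invariant under re-normalization.
* Discretization: 32 equal-width bins over the VOI min–max. Bin count
  fixed across channels.

## Radiomics features

174 features per sample: 14 shape + 18 first-order + 22 GLCM from the
pre-contrast channel and 18 + 22 from each map channel. Shape depends
only on the mask and therefore appears once (the 54 + 3×40 = 174
arithmetic forces this). Conventions chosen where the literature
varies, each matched by the brute-force oracles in the test suite:

* Surface quantities come from a marching-cubes mesh of the mask.
  The binary 0/1 isosurface inflates the area of smooth objects by
  ~9% (staircase effect), so the mask is pre-filtered with a Gaussian
  of 0.8 voxel SD before meshing; a digital ball of radius 10 mm then
  gets sphericity 0.99 instead of 0.91. Masks too small to survive
  the filter fall back to the raw isosurface.
* Axis lengths are `4·sqrt(λ)` of the voxel-coordinate covariance
  eigenvalues (population covariance); a single voxel has diameter 0
  and elongation/flatness 1 by definition.
* Maximum 2D diameters are the largest in-plane extents over planes
  normal to each axis.
* First-order: population variance; Pearson (non-excess) kurtosis;
  skewness/kurtosis defined as 0 for constant input; entropy and
  uniformity computed on the 32-level histogram.
* GLCM: 13 offsets at Chebyshev distance 1, symmetric accumulation,
  features computed per offset and averaged over offsets that contain
  pairs; a degenerate matrix (single occupied level) has correlation
  defined as 1.

## Consensus subtyping

Z-scoring uses the sample SD; zero-variance columns are dropped with
a warning and the scaling is retained for out-of-cohort application.
PAM is the classic BUILD+SWAP with all ties broken toward the lowest
index, making the whole consensus run a deterministic function of the
seed. Each of the default 500 repetitions (300 in the acceptance
runs; the reference analysis used 10,000 — consensus values are
Monte-Carlo estimates either way) draws 80% of samples and 80% of
features **without replacement**, one draw shared by all k. Pairs
never co-sampled get consensus 0 with a warning; at 80% sampling and
≥100 repetitions this is vanishingly rare.

**Cluster-number rule.** The CDF area `A(k)` is computed on a fixed
100-bin grid; the relative increment is `Δ(k) = (A(k) −
A(k−1))/A(k−1)` with `Δ(k_min) = A(k_min)`. The selected k is the
largest with `Δ(k) ≥ 0.10` (configurable). The threshold deserves
justification: for n samples in three balanced, perfectly separated
clusters, going from k = 3 to k = 4 must split one true cluster, and
the ~1/9 of sample pairs inside it move from consensus 1 to roughly
0.5, which raises the CDF area by ≈ 0.05 on a base of ≈ 0.66 — a
*relative* increment of 6–9% that no amount of separation removes.
A threshold below that (e.g. the 2.5% sometimes quoted for this rule)
can therefore never stop at the true k under balanced designs; 0.10
sits between this geometric floor and the Δ ≈ 0.4 observed at the
true cluster number. Edge cases (no k above threshold, all k above)
fall back to min/max of the range and are flagged low-confidence.

Final labels cut an average-linkage tree of `1 − consensus`; the IGP
centroid model stores per-cluster mean z-scored vectors plus the
scaling. Validation samples are assigned to the centroid with the
highest Spearman correlation (ties to the lowest cluster index); a
group that attracts no samples reports IGP = NaN.

## Statistics

Thin wrappers fix conventions: one-way fixed-effects ANOVA; Tukey HSD
via the studentized range; Student's t with pooled variance (Welch by
flag); t-distribution 95% CIs. The chi-squared/Fisher switch follows
the standard expected-count rule (any expected cell ≤ 5 → Fisher),
and the method that ran is always reported. For tables larger than
2×2 no closed-form exact test is practical; the package runs a
conditional Monte-Carlo test (random tables with the observed
margins, p = proportion at most as probable as the observed table,
20,000 draws, seeded), reported as `fisher_mc`. No multiplicity
correction is applied to per-feature ANOVA scans by default; the gene
selection in the expression bridge does use Benjamini–Hochberg.

The log-rank test uses the asymptotic chi-square reference (k−1 df,
unstratified). It is known to be mildly anti-conservative below ~20
events per group (~6% size at 15/group in our null simulations); the
calibration suite therefore runs its null at 50 events per group,
where the asymptotics hold.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes
— not scanner physics. Design, per sample:

* **Geometry** — a randomly oriented ellipsoid with axis ratios in
  [0.6, 1], volume drawn from the phenotype's `N(mean, sd)` (means
  1458.66 / 8564.07 / 8258.59 mm³ for S1/S2/S3, the subtype mean
  volumes the analysis is calibrated to; SDs 300/1500/2000 mm³), a
  smooth boundary perturbation, and the largest connected component
  kept. Draws whose short axis exceeds the 32-voxel z slab are
  flattened at constant volume (large breast tumors are commonly
  oblate in the slab direction); an in-plane overflow raises a sizing
  error. Default grid 64×64×32 at 1 mm isotropic, so resampling is
  near-identity and a 60-sample cohort generates in seconds.
* **Kinetics** — the tumor PE field is `pe_mean · (1 + 0.3·G +
  w·R)` where G is a unit-variance Gaussian random field with the
  phenotype's correlation length (1.2 / 6.0 / 3.0 mm), R a
  standardized radial profile (high at the boundary) and w the rim
  weight (0 / +0.7 / −0.7): S2 rim-enhances, the radiological
  signature of rapidly enhancing malignant lesions, S3 is mildly
  core-weighted, S1 homogeneous. Both fields are standardized within
  the mask, so the pre-noise tumor-mean PE equals the target exactly
  up to the clipping that keeps PE ≥ 1 (worst case +8% for S2). The
  late volume is placed so the voxelwise SER field has the target
  mean (1.0 / 1.6 / 1.05); middle SER interpolates halfway between 1
  and the late value. Background enhances at PE = 5.
  The deterministic rim/core component matters: VOI-wise μ±3σ
  normalization removes pure level differences between phenotypes, so
  without it the phenotypes would differ only through the correlation
  length of a random field — a realization-noisy signature that left
  cluster boundaries ambiguous. With it, the three phenotypes are
  cleanly separable (consensus clustering recovers them at ARI 1.0
  and the identical-cohort IGP is exactly 100%, checked over 18
  seeds).
* **Noise** — additive Gaussian (SD 2 on a baseline of 100), not
  Rician; at this SNR the Rice distribution is indistinguishable from
  Gaussian and the additive model keeps the calibration exact in
  expectation.
* **Expression** — negative-binomial counts (dispersion 0.1),
  log-normal baseline means around 50, 100 informative genes out of
  2000 with per-subtype shifts of ±1 log2 unit (one subtype up, one
  down, one unchanged, randomly assigned per gene). The gene model —
  which genes are informative, their shift pattern and baseline
  means — is drawn from a dedicated `gene_model_seed` shared across
  cohorts, so independent cohorts represent new samples from the same
  biology and a classifier trained on one transfers to another, as
  the cross-cohort analysis requires.
* **Survival** — exponential event times with hazards 0.05 / 0.20 /
  0.10 per time unit for S1/S2/S3 (prognosis ordering S1 best, S2
  worst, S3 intermediate); with probability `censor_rate` (default
  0.2) a sample is censored uniformly over its own follow-up.

What the generator does **not** emulate: scanner physics (k-space,
coil bias, motion), partial-volume effects, multi-center intensity
shifts, non-ellipsoidal or infiltrative tumor morphology, correlation
between imaging phenotype and expression beyond the shared subtype
label, and non-proportional hazards. Passing tests therefore show the
pipeline is correct and recovers structure of this planted kind; they
say nothing about subtype existence in any real cohort.

## Problem sizes

The test suite and acceptance script run 60-sample cohorts with 300
consensus repetitions over k = 2…8 and 10 generation seeds, 2000-rep
statistical null simulations, and an expression bridge at n = 150
with a 2000-tree forest — sizes chosen so the full suite completes in
a few minutes on one CPU while keeping every Monte-Carlo tolerance
meaningful. All sizes are configurable upward.

## Known limitations

* The 14/18/22 feature sets follow one common IBSI-aligned selection;
  other extractors bin, aggregate and name slightly differently, so
  absolute feature values are comparable only within this package.
* Consensus values at 300–500 repetitions carry Monte-Carlo noise of
  a few percent; the delta-area trace is stable but not bit-stable
  across repetition counts.
* The r×c Fisher branch is Monte-Carlo, not exact; its p-values have
  simulation error ~1/√20000.
* The IGP analytic guarantee (identical cohorts → 100%) holds when
  nearest-centroid assignment reproduces the discovery partition; on
  data with genuinely overlapping clusters the observed IGP drops
  below 100 even in the identical-cohort setting, which is the
  statistic working as intended.
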