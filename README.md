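# radsubtype

Unsupervised imaging-subtype discovery from breast DCE-MRI radiomics.

Dynamic contrast-enhanced MRI captures how tissue takes up and washes
out contrast agent. `radsubtype` turns a registered 4-timepoint series
(pre-contrast, early, middle, late) plus a tumor mask into voxel-wise
kinetic maps, summarises each tumor as a 174-dimensional radiomics
vector, discovers imaging subtypes without supervision, validates them
across cohorts, and links them to gene expression and survival. It is
aimed at radiogenomics researchers who want a tested, reproducible
reference implementation of this analysis, exercised end to end on a
built-in synthetic cohort generator.

## The method

**Kinetic maps.** Per voxel, with signal intensities `I`:

- early percentage enhancement `PE = 100 · (I_early − I_pre) / I_pre`
- signal enhancement ratio `SER = (I_early − I_pre) / (I_map − I_pre)`
  for the middle and late phases (`SER > 1` is washout, `≈ 1`
  persistent enhancement)

Degenerate voxels (`I_pre ≈ 0`, `I_map ≈ I_pre`) are set to 0 and
flagged invalid rather than producing infinities.

**Features.** Images and maps are resampled to 1 mm isotropic (cubic
B-spline; nearest neighbour for masks), normalized within the tumor
VOI to fit `μ ± 3σ`, and discretized to 32 gray levels. The feature
vector is exactly 174 entries: 14 shape + 18 first-order + 22 GLCM
texture features from the pre-contrast image, and 18 first-order + 22
GLCM from each of the early-PE, middle-SER and late-SER maps.

**Subtyping.** Features are z-scored and clustered by consensus
resampling: many 80%-of-samples × 80%-of-features subsamples, each
clustered by partitioning-around-medoids (PAM) over Spearman distance
for k = 2…8. The consensus value of a sample pair is the fraction of
co-sampled runs in which they co-cluster; the cluster number is chosen
by the relative change in area under the CDF of consensus values
(delta-area elbow); final labels come from average-linkage clustering
of the consensus matrix. Reproducibility in a second cohort is
measured by the in-group proportion (IGP): validation samples are
assigned to the nearest discovery centroid by Spearman correlation,
and IGP per group is the percentage whose nearest neighbour shares the
group (100% = clusters perfectly reproduced).

**Expression bridge.** Subtype-specific genes are selected by per-gene
one-way ANOVA (Benjamini–Hochberg, log2(x+1) counts); a 2000-tree
random forest predicts imaging subtypes from expression alone
(evaluated by micro-averaged multi-class AUC) so that survival can be
compared across predicted subtypes (Kaplan–Meier + log-rank) in
cohorts that lack imaging.

**Synthetic cohorts.** The generator plants three phenotypes matching
the reported imaging subtypes — S1 small/general enhancement
(1458.66 mm³ mean volume), S2 large/rapid enhancement with washout
(8564.07 mm³, SER 1.6, rim-enhancing), S3 large/general enhancement
(8258.59 mm³, core-weighted) — with phenotype-specific texture
correlation lengths, matched negative-binomial expression with
informative genes, and exponential survival ordered S1 > S3 > S2.

## Worked example

```bash
radsubtype simulate --out cohort/ --n 60 --seed 7
radsubtype features --cohort cohort/ --out cohort/features.csv
radsubtype cluster  --features cohort/features.csv \
                    --out cohort/subtypes --reps 300 --seed 7
radsubtype survival --survival cohort/survival.csv \
                    --labels cohort/subtypes/labels.csv
```

printed (60 synthetic samples, seed 7):

```
wrote cohort of 60 samples to cohort/
wrote 60 x 174 feature table
optimal k = 3; labels in cohort/subtypes/labels.csv
log-rank chi2 = 34.810, p = 2.762e-08
```

The delta-area trace behind `optimal k = 3` was
`{2: 0.457, 3: 0.489, 4: 0.084, 5: 0.063, 6: 0.024, 7: 0.022, 8: 0.019}`:
the area under the consensus CDF grows sharply up to three clusters
and only marginally beyond, so three imaging subtypes are selected
(20/20/20 samples — the generator's balanced planted phenotypes). The
log-rank p ≈ 3e−8 says the three discovered subtypes stratify the
simulated survival strongly, with S2 (large, rapidly enhancing) worst,
as its higher hazard dictates.

The same steps are available as library calls (`generate_cohort`,
`build_feature_table`, `consensus_cluster`, `igp_validate`,
`km_logrank`, …) — see the module docstrings.

## Layout

- `src/radsubtype/maps.py` — PE/SER maps, subtraction segmentation
- `src/radsubtype/prep.py` — resampling, μ±3σ normalization, binning
- `src/radsubtype/features/` — shape, first-order, GLCM kernels and
  the 174-feature assembly
- `src/radsubtype/cluster.py` — PAM, consensus clustering, delta-area
  rule, IGP, PCA contributions
- `src/radsubtype/stats.py` — ANOVA/Tukey/t/CI/association tests
- `src/radsubtype/bridge.py` — gene selection, random-forest subtype
  classifier, micro AUC, Kaplan–Meier/log-rank
- `src/radsubtype/synthetic.py` — the three-phenotype cohort generator
- `docs/methods.md` — modelling assumptions, parameter choices and
  known limitations
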