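# Methods

This note documents the models behind `idcpheno`, the choices made
where the design was genuinely open, and what the synthetic study
conditions do and do not establish about real field data.

## Imaging model

**Segmentation.** Images are converted to HSV (hue in degrees,
[0, 360)) and a pixel is kept as foreground when its saturation is at
least `saturation_min` (default 0.15) and its hue falls in a kept
range (default [10°, 160°), brown through green). Soil is gray —
low saturation — and weeds/debris occupying other hues drop out by the
hue rule. Both thresholds are exposed in `SegmentationParams`: the
defaults are sensible for canopy imagery but any deployment against a
new camera/soil combination should re-examine them. After
thresholding, only the largest connected component is retained
(8-connectivity by default; configurable to 4). Equal-area ties are
broken toward the component whose first pixel occurs earliest in
row-major order, which makes the cleanup deterministic.

**Calibration.** Color-chart correction is a per-channel affine map
(gain, offset) fitted by least squares over the 24 chart patches. A
full 3×3 color matrix would also be defensible; the affine form is the
minimal model that corrects illumination drift without cross-channel
coupling, and calibration is optional — images pass through unchanged
when no chart is supplied. A channel with zero variance across patches
degrades to the identity with a warning.

**Features.** Y% and B% are percentages of canopy-mask pixels whose
hue falls in the yellow band [40°, 70°) and brown band [10°, 40°);
green occupies [70°, 160°). All bands are half-open so each pixel
belongs to at most one band. Mask pixels outside all three bands
count toward the denominator only, which keeps Y% + B% ≤ 100. An
empty mask raises rather than returning (0, 0): a silent zero would be
indistinguishable from a healthy canopy.

## Synthetic canopies

The generator emulates the statistical structure the imaging stages
must cope with, not photorealism: a connected blob of leaflet disks
over low-saturation soil, small brown debris blobs disjoint from the
canopy, and multiplicative illumination jitter. Exactly
`round(yellow_frac · area)` canopy pixels receive yellow-band hue
(similarly brown); colors are drawn from band *interiors* with ≥ 5°
margin so 8-bit quantisation cannot cross a band boundary, and soil
saturation stays below 0.11 by construction. Ground-truth percentages
are re-counted from the emitted image, so they are exact by
definition. Consequences worth keeping in mind:

- Segmentation and feature extraction are exact on these images; the
  pipeline's P/R ≥ 0.99 margin exists for real-world effects
  (shadows, mixed soil/leaf pixels) the generator does not produce.
- The generator cannot encode stunting, which contributes to field
  scores 4–5; a top-down color image has no height information. The
  fixture label rule below is therefore a color-only surrogate.
- Overlapping plots, specular highlights and RAW decoding are out of
  scope.

**Fixture label rule.** Training labels for synthetic sets derive
from (Y%, B%) by fixed cutoffs evaluated most-severe first: B ≥ 15 →
5; Y ≥ 50 or B ≥ 5 → 4; Y ≥ 25 or B ≥ 2 → 3; Y ≥ 5 or B ≥ 1 → 2;
else 1. These are generator parameters defining the synthetic study,
not estimates of any field rubric. Class-conditional clusters sit ≥ 5
within-class standard deviations apart, with mild imbalance toward
score 1 (32%) echoing field panels dominated by healthy plots.

## Classifier

Stage 1 is a joint multiclass linear margin (Crammer–Singer) over
z-scored (Y%, B%), producing one linear score per susceptibility group
with argmax decision; stage 2 uses ordinary binary linear SVMs for
1-vs-2 and 4-vs-5. The joint formulation was chosen over independent
one-vs-rest fits because the medium group occupies a *strip* between
low and high in feature space: each OvR subproblem is then
non-separable on its own and the combined decision leaves a small
residual error even on cleanly separated clusters, whereas the joint
margin separates them exactly. The soft-margin constant `C` (default
1.0) is shared by all stages and config-exposed. Features are
standardised with training statistics. Groups degenerate gracefully:
a stage seeing one label becomes a constant predictor with a warning.

Evaluation uses the 5×5 confusion matrix: overall accuracy
(trace/total), per-class accuracy (diagonal over row total, equal to
one-vs-rest sensitivity), average per-class accuracy over classes
present in the test set, and one-vs-rest specificity. The
train/test split is stratified (75/25 by default) because the fixture
— like field data — is imbalanced; classes with fewer than two members
go wholly to training with a warning.

## Severity

Severity is `clip(w1·B% + w2·Y%, 0, 100)` with `w1 ≥ w2 ≥ 0`:
necrosis marks later-stage damage than chlorosis and never receives
the smaller weight, the origin maps to 0 (no symptoms) and a fully
necrotic canopy to 100. `w1` is pinned at 1.0 as the scale anchor —
the two anchors would otherwise be violated by any additional scale
parameter — and `w2` is searched on [0, 1] in steps of 0.01. For each
candidate, the four score-band cutpoints minimising misclassification
are found by an exact dynamic program over the sorted severity values
(each DP layer is a prefix minimum, so the solve is O(n) per score);
this is equivalent to exhaustive search over adjacent midpoints, which
the test suite uses as an independent oracle on small fixtures. Ties
across `w2` candidates resolve to the smallest weight, making refits
deterministic and row-order invariant. Empty score bands produce
coincident boundaries, repaired to strictly increasing cutpoints by
epsilon nudges.

## Genotype and trait simulation

Panels are fully inbred: one haplotype per line, dosage coded {0, 2}
so VanRaden formulas apply unchanged. LD is a first-order
copy-with-probability chain along each chromosome (allele *j* copies
allele *j−1* with probability `ld_rho`, default 0.6, else redraws at
the SNP's target frequency). This produces adjacent-marker
correlation ≈ `ld_rho` when neighbouring frequencies are similar —
enough to exercise r² > 0.2 clumping — but no recombination-map
realism, no population structure and no multi-allelic sites.

The trait is `value = μ + g + rep + e` in a balanced randomized
complete block design (default 4 reps, matching common IDC nurseries).
The genetic value sums planted QTL effects and a polygenic term
`W·c` (kinship-correlated by construction), then is rescaled so the
line-mean heritability `Var(g) / (Var(g) + σ²ₑ/r)` equals the target
`h2` (default 0.6, an intermediate value typical of IDC ratings)
against the stated residual variance. `effect_for_target_r2` inverts
this bookkeeping to plant a QTL explaining a chosen fraction of
line-mean phenotypic variance. The SPAD-like surrogate is
`40 − 5·(r·z + √(1−r²)·noise)`-shaped per line with
corr(surrogate, genetic value) = −`spad_corr` (default 0.6; greener =
healthier), available to prediction models as a fixed covariate.

## BLUPs

Line BLUPs come from the two-way random model `value = μ + line + rep
+ e`. For balanced data the closed-form ANOVA estimators are used —
they coincide with REML under balance — and the BLUP is
`μ + shrink·(line mean − μ)` with `shrink = r·σ²g / (r·σ²g + σ²e)`.
Unbalanced tables fall back to a dense numerical REML (Nelder–Mead
over the two variance ratios), intended for modest n since it forms
the full covariance. Zero between-line variance degrades to all-BLUPs
-equal-the-mean with a warning. The suite cross-checks the balanced
path against R's `lme4` as an independent reference.

## Mixed linear model scan

The association model is `y = μ + xα + u + e`, `u ~ N(0, 2K·Vg)`,
`e ~ N(0, I·Ve)`, with `K` the VanRaden genomic relationship matrix
(monomorphic SNPs excluded from both the centered matrix and the
denominator). The `2K` scaling of the random-effect covariance is
followed as printed in the standard formulation. Variance components
are estimated once by REML on the marker-free null model via a single
spectral decomposition of `2K` — profiling on the ratio
`δ = Ve/Vg`, coarse log-grid then bounded scalar refinement to
`xatol = 1e-6` — and reused for every marker
(population-parameters-previously-determined). Each marker is then
tested by GLS with the fixed covariance; the per-marker solve is
vectorised through the same rotation, so a 400 × 2,000 scan takes a
fraction of a second. When `Vg = 0` and `K ∝ I` the scan reduces
exactly to per-SNP OLS, which the suite asserts to 1e−10.

Principal-component fixed effects are supported (`n_pcs`) but default
to 0: diverse inbred panels of this kind typically show no structure
requiring them, and the degenerate default keeps the null model
minimal. Per-SNP R² is deliberately from the *ordinary* regression of
y on the SNP alone — the conventional "variance explained in a general
linear model" — not from the mixed model. Monomorphic SNPs are
reported with p = 1 and a flag rather than dropped, so scan output
always aligns with the input map. The ordinal score is treated as a
continuous response throughout the BLUP and MLM stages; this mirrors
common practice for 1–5 severity ratings but is a documented
approximation, not an ordinal model.

Significance is Benjamini–Hochberg at q = 0.05 (via
`statsmodels.stats.multitest`). Clumping is greedy: lowest-p
remaining SNP becomes a peak and absorbs same-chromosome significant
SNPs with r² > 0.20 to the peak; cross-chromosome r² never merges
clusters. LD r² is the squared Pearson correlation of dosage vectors,
which for inbreds equals haplotype r². Phase classification counts a
line as coupling when its alleles at two loci are both favorable or
both unfavorable; heterozygous or missing lines are excluded from the
denominator with a warning.

## RR-BLUP

`y = Xβ + Zu + e` with `Var[u] = Iσ²ᵤ`: every marker is a random
effect with common variance, the identity playing the role of the
marker covariance. The shrinkage ratio `λ = σ²ₑ/σ²ᵤ` is REML-estimated
on the spectral form of `ZZ′` (same machinery as the MLM, O(n)
per likelihood evaluation after one n×n eigendecomposition); with λ
fixed by the caller the solution is the exact closed form
`u = Z′(ZZ′ + λI)⁻¹(y − Xβ)`, verified against the dense
mixed-model-equation solve to 1e−8 and against GBLUP genomic values to
1e−6. Marker columns are centered once, globally; with an intercept
in X the centering constant is absorbed, so predictions are unchanged
and per-fold re-centering during cross-validation is unnecessary.

**Cross-validation.** Lines are partitioned into k = 10 folds by a
seeded shuffle (no stratification); λ is re-estimated within each
training fold; accuracy is the Pearson correlation between the trait
values and the pooled out-of-fold predictions. Held-out lines'
*fixed covariates* (major-QTL genotype, surrogate trait) are used at
prediction time: both are observable without the phenotype being
predicted. This is stated prominently because it inflates accuracy
relative to genotype-only prediction — it answers "what can I predict
for a new line I have genotyped and SPAD-measured", not "genotyped
only". The fixed QTL column is specified globally rather than
re-selected inside each training fold, matching the
workflow where the locus is known beforehand; re-running GWAS per fold
would be the stricter, leakage-free protocol and can be composed from
the library pieces.

**Null-accuracy bias.** With no heritable signal the marker effects
shrink to ~0 and each fold's predictions collapse toward its training
mean; pooled-Pearson accuracy is then biased toward −1/√(fold size)
(≈ −0.29 at fold size 12), not 0. This is an artifact of the pooled
correlation that the standard definition carries; the suite tests the
meaningful null property (no positive skill) and real comparisons
should always be read against a matched null, not against zero.

## Problem sizes

Test and acceptance runs use scaled-down panels chosen as realistic
exercises of each property: 50 images for segmentation/extraction
fidelity, 1,000 labeled images for the classifier, 20 replicates of
n = 400 lines × m = 2,000 SNPs with a 9%-variance QTL for GWAS
recovery and null calibration, and 20 replicates of n = 300 × 1,000
with a 10%-variance QTL plus a 0.6-correlated surrogate for the
prediction ladder. The full suite and the acceptance script each run
in well under a minute of compute per stage on one CPU.

## Known limitations

- Hue-band defaults (and the saturation threshold) are package
  defaults, not field-calibrated values; real deployments should tune
  them per camera and soil.
- The severity weight search assumes the two anchors and linearity;
  nonlinear severity maps are out of scope.
- The LD model has no recombination-rate variation; clumping behaviour
  on real SoySNP50K-like data will differ in block sizes.
- The MLM treats the ordinal score as Gaussian; no ordinal-link model
  is provided.
- No BEAGLE-style haplotype imputation: missing genotypes are imputed
  to the per-SNP mode after the missing-rate filter, which is adequate
  at the low missingness the QC admits (≤ 10%) but weaker than
  haplotype-based imputation near that boundary.
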