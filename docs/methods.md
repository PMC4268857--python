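# Methods

## Stromal-fraction estimation from H&E images

The segmenter assumes brightfield H&E tiles in which background is flat and
bright, tissue is textured, carcinoma is haematoxylin-dominant (basophilic,
nucleus-rich) and stroma is eosin-dominant (collagenous). The steps:

* **Tissue masking.** Local Shannon entropy (bits) of the 256-level luminance
  image (weights 0.299/0.587/0.114) in a disk window of radius 5 px. The
  default threshold is Otsu on the entropy map; a fixed threshold (default
  4 bits) is available for images whose entropy histogram is not bimodal,
  e.g. all-noise or all-flat inputs. Pixels above threshold are tissue.
* **Stain unmixing.** Optical density `od = -log10(max(I,1)/I0)` per channel
  with background intensity `I0 = 255` by default; concentrations solve
  `M·c = od` where the columns of `M` are the unit-normalised Ruifrok H&E
  vectors H = (0.650, 0.704, 0.286), E = (0.072, 0.990, 0.105), with a
  residual third vector completed by cross product. The per-pixel
  reconstruction residual is returned for QC.
* **Stromal signal and threshold.** The raw stromal signal is `E − H`
  (eosinophilic stroma positive). Otsu's threshold is computed over tissue
  pixels only, on the interior edges of a 256-bin histogram, maximising the
  between-class variance of the actual values (not bin centres); ties go to
  the lowest edge. An optional median filter (disk radius 3) can pre-smooth
  the signal.
* **Smoothing and fraction.** Morphological opening then closing (disk radius
  2) on the thresholded stroma mask; "smoothing" could equally be read as
  pre-threshold filtering, so both are offered, with the post-threshold
  morphology as the deterministic default. The stromal fraction is
  stroma/tissue pixel counts. Fewer than 64 tissue pixels yields an undefined
  fraction with a `no-tissue` flag rather than a silent zero.

Rotation by multiples of 90° changes the estimate by < 0.02 on test tiles;
coordinates are row-major with origin top-left and masks share the image
shape. Whole-slide pyramidal formats, nuclei segmentation and cross-scanner
colour normalisation are out of scope.

## Linking fractions to expression

Signature scores default to per-gene z-scoring before averaging so that
highly expressed genes do not dominate; a raw-mean mode exists. Correlation
p-values are two-sided from the t transform with n−2 df, and gene ranking
sorts by signed r descending. The Jonckheere–Terpstra statistic
`J = Σ_{k<l} #{x_k < x_l} + ½#{x_k = x_l}` is tested by seeded label
permutation (default 10⁴ permutations; the p-value uses the add-one
estimator) with a tie-corrected normal approximation for large cohorts.
Quantile bins use type-7 empirical quantiles with boundary ties going to the
lower bin, so bin labels are deterministic. Prediction of stromal content
from signature scores is an ordinary least-squares line fit on the samples
with images (at least 10 required), with predictions clipped to [0, 1]; the
functional form is an explicit modelling choice — nothing in the data demands
linearity, but it is the simplest defensible calibration and its diagnostics
(slope, intercept, r) are returned for inspection.

## Stroma-corrected differential expression

The contrast takes the bottom and top quartiles of the gene of interest.
The moderated t shrinks gene-wise pooled variances toward the cohort mean
variance s₀² with `prior_df` pseudo-observations (default 4):
`s²_mod = (d₀·s₀² + d·s²)/(d₀ + d)`, referred to a t distribution with
`d + d₀` df. This is a deliberately simple empirical-Bayes scheme — the full
hierarchical variance model used by dedicated DE packages is not re-derived —
and `prior_df = 0` recovers the classical pooled t exactly, which is how the
implementation is oracle-tested. FDR control is Benjamini–Hochberg
(step-up, monotone, capped at 1). The top-50 selection orders by ascending p
with ties broken by |difference| then gene id, and heat-map ordering comes
from Ward linkage on Euclidean distances.

GSEA uses the classic (weight-0) Kolmogorov–Smirnov running sum: hits add
1/m, misses subtract 1/(N−m), ES is the signed maximal deviation; weight 1
(|score|-normalised increments) is available. The ranking score is the
signed moderated t. The permutation p (default 1000 gene-label permutations,
seeded) is one-sided for positive enrichment.

The compartment-deconvolved contrast regresses each gene on the two-column
design (f, 1−f) within each group by least squares, giving stroma- and
tumour-compartment expression; the contrast is the between-group difference
per compartment. Significance is a plug-in FDR over the observed |difference|
thresholds: median false-call count across seeded group-label permutations
(default 200) divided by the observed call count, capped at 1. Constant
fractions within a group make the design rank-deficient and raise.

## Survival and association statistics

Cox regression maximises the Breslow partial likelihood by Newton–Raphson
(tolerance 1e-8 on the step, max 50 iterations, covariates centred for
conditioning; a diverging coefficient sets a `separation-suspected` flag).
Breslow tie handling was chosen for transparency and oracle-testability;
with continuous event times it coincides with Efron, which is how the fit is
cross-checked against an independent survival library. With `use_entry`, the
risk set at time t is `{entry < t ≤ exit}`, the delayed-entry correction for
left truncation: subjects who died before their study entry are never
observed, and ignoring that (with uniform entry and near-exponential
hazards) demonstrably biases the marker effect — the package's simulation
shows the naive fit overshooting the true log hazard ratio while the
delayed-entry fit stays centred. Wald intervals are `exp(β ± 1.96·SE)`.
Stage and grade enter as ordinal numerics, site as treatment-coded dummies.
Kaplan–Meier estimation (with the same delayed-entry risk sets) is delegated
to lifelines.

Fisher's exact test is the hypergeometric two-sided test for 2×2 tables and
seeded Monte-Carlo with fixed margins (Patefield sampling) for R×C, counting
tables no more likely than the observed one; the binomial standard error of
the estimate is reported. The chi-squared test is Pearson's without
continuity correction and warns when any expected count is below 5. The
Wilcoxon rank-sum test enumerates exactly for tie-free pooled samples up to
25 observations, otherwise uses the tie-corrected normal approximation.
Median dichotomisation sends values equal to the median low.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions; they are deliberately simple
forward models, not photorealistic simulators.

* **Tiles** (128×128 default): tissue is a thresholded smooth Gaussian field
  covering ~72% of the tile; the stromal subregion is carved by thresholding
  a second smooth field, with the threshold bisected until the achieved
  fraction is within 0.02 of target. Tumour renders with haematoxylin
  concentration 1.0 plus nuclear speckle, stroma with eosin 0.9 plus
  anisotropic fibre texture; both get 20% multiplicative jitter.
  RGB = 255·10^(−M·c) plus Gaussian pixel noise (sd 1.5), quantised to
  8 bits. Real histology has nuclei in stroma, mixed boundary pixels,
  scanner-dependent stain vectors and focal artefacts — none are modelled,
  so passing segmentation tests demonstrates correctness of the algorithm on
  its assumed forward model, not clinical-grade accuracy.
* **Expression** (300 samples × 2000 genes default): log2 mixtures
  `x = f·s + (1−f)·t + ε` with f ~ Beta(2, 2) and ε ~ N(0, 0.5²).
  The 100 signature genes (including ACTA2) have stromal mean 10 vs tumour
  mean 5 (log2); other genes are N(7, 1) in both compartments with 0.3
  per-sample tumour wobble. Tumour PTEN is 8 + log2(copy factor) with
  factors 0.1 / 0.55 / 1.0 for homozygous deletion / hemizygous loss /
  diploid at probabilities 0.06 / 0.36 / 0.58; stromal PTEN is constant at
  9. Tumour AR couples to standardised tumour PTEN with ρ = 0.4. The copy
  factors and ρ are invented defaults chosen to make the
  confounding-then-correction pattern reproducible at desk scale; they are
  config-exposed and not measurements. Real cohorts add batch effects,
  heavier-tailed noise and many cell types beyond two compartments.
* **Staining**: a copy-state-conditional confusion matrix concentrating
  homozygous deletion on negative staining, hemizygous loss on
  weak/heterogeneous, diploid on positive.
* **Survival**: exponential baseline hazard 0.012/month (median ≈ 58 months),
  hazard ratio 1.8 for reduced PTEN, entry ~ Uniform(0, 36) months with
  (entry, event-time) pairs redrawn until the subject survives past entry —
  the standard delayed-entry conditioning — and administrative censoring at
  120 months. Age N(58, 8), stage/grade/site frequencies follow the primary
  cohort's marginal distributions and carry no true hazard effect, so the
  adjusted model's marker coefficient is the estimand.

Every generator is a pure function of (config, seed) and regenerates
bit-identically.

## Problem sizes and numerical choices

The default replay uses 20 imaged tiles, a 300×2000 cohort, 1000 GSEA and
200 csSAM permutations, and survival cohorts of 600 with 50 replicates for
interval-coverage checks — sizes chosen so the full suite and the
reproduction script each run in well under a minute while leaving the
statistical assertions comfortable margins. Seeds for sub-steps are derived
from one master seed via a PCG64 stream and kept below 2³¹. The single-draw
hazard-ratio estimate at n = 600 has SE(log HR) ≈ 0.12, so point estimates
scatter roughly ±25% around 1.8; the median across the 50 replicates is the
stable summary.

Known limitations: no Efron tie correction or proportional-hazards
diagnostics; GSEA reports a single set (no cross-set FDR); the entropy
threshold and stain basis are global per image; quantile conventions other
than type-7 are not offered.
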