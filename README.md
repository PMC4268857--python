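# stromalens

Stroma-aware analysis of tumour sections and expression profiles.

Bulk expression profiles of solid tumours mix carcinoma cells with stroma, and
for genes the stroma itself expresses — PTEN being the motivating case in
high-grade serous ovarian carcinoma — that admixture masks tumour-cell loss:
samples rich in stroma look PTEN-high regardless of the tumour cells' copy
state. `stromalens` implements the integrative recipe for resolving this:

1. **Image segmentation** — estimate the stromal area fraction of an H&E tile:
   an entropy filter separates textured tissue from background, the RGB image
   is converted to optical density (Beer–Lambert, `od = -log10(I/I0)`) and
   unmixed with the Ruifrok H&E stain basis, the raw stromal signal `E − H`
   (eosin minus haematoxylin concentration) is thresholded by Otsu's method
   within tissue, and morphological smoothing yields the stroma mask; the
   fraction is `|stroma| / |tissue|`.
2. **Signature calibration** — score a stromal gene signature per sample
   (mean z-scored expression), regress image-derived fractions on the score,
   and predict stromal content for samples without images; per-gene Pearson
   correlations rank stromal markers (ACTA2 in the canonical application), and
   a permutation Jonckheere–Terpstra test checks the trend against ordinal
   manual bins.
3. **Stroma-corrected differential expression** — contrast top vs bottom
   quartiles of the gene of interest with a moderated t statistic
   (`s²_mod = (d₀s₀² + d·s²)/(d₀+d)`), Benjamini–Hochberg FDR, Ward/Euclidean
   clustering of the top 50 genes, the classic GSEA running-sum enrichment
   score of the stromal set, and a csSAM-style compartment-deconvolved
   contrast that regresses each gene on the `(f, 1−f)` mixing design with a
   permutation plug-in FDR. Repeating the contrast inside the lowest ACTA2
   quartile removes most stromal enrichment.
4. **Left-truncated survival** — staining categories (negative / weak /
   heterogeneous / positive) are dichotomised into reduced vs retained marker
   expression; Kaplan–Meier curves and a Newton–Raphson Cox model (Breslow
   ties) use delayed-entry risk sets `{entry < t ≤ exit}` so deaths before
   study entry do not bias the hazard ratio; Fisher, chi-squared, Wilcoxon and
   t tests cover the contingency analyses.
5. **Synthetic data** — every input is generated with known ground truth:
   H&E-like tiles with controlled stromal fraction, two-compartment expression
   mixtures `x = f·s + (1−f)·t + ε` in which tumour PTEN tracks copy state
   (homozygous deletion 6%, hemizygous loss 36% by default) while stromal PTEN
   is constant, staining categories drawn from a copy-state confusion matrix,
   and survival tables with a true hazard ratio of 1.8 for reduced-PTEN cases
   under left truncation.

The package is a library first (`import stromalens`); `examples/` holds one
short narrative script per capability, and a thin `stroma-lens` CLI
(`simulate | segment | full-run`) wraps the pipeline for shell use.

## Worked example

```sh
python examples/stroma_corrected_de.py
```

prints

```
observed PTEN ~ ACTA2 Pearson r: 0.322 (tumour PTEN is independent of stroma by construction)
stromal-set enrichment, all samples:      ES=0.932 (p=0.0010)
stromal-set enrichment, ACTA2-low subset: ES=0.402 (p=0.0010)
enrichment drop: 57%
```

Observed PTEN correlates with the stromal marker ACTA2 (r = 0.32) even though
tumour-cell PTEN was generated independently of stromal content — the
correlation is pure admixture. The PTEN-quartile contrast is therefore
dominated by stromal genes (enrichment score 0.93); restricting the contrast
to the lowest ACTA2 quartile drops the enrichment to 0.40, showing the
correction isolates tumour-cell differences. Similarly,

```sh
python examples/survival_left_truncation.py
```

```
true hazard ratio: 1.8
delayed-entry Cox: HR=1.78 (95% CI 1.49-2.13), n=600, events=490
naive Cox (entry ignored): HR=1.87
```

recovers the simulated hazard ratio for reduced PTEN once delayed entry is
modelled, while the naive fit is biased.

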