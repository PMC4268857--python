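"""End-to-end orchestration of the stroma-aware analysis.

``run_full_analysis`` replays the whole study design on a synthetic cohort
with known ground truth: segment H&E tiles, calibrate a stromal signature
against the image-derived fractions, rank stromal genes, contrast PTEN
quartiles (on all samples and within the lowest ACTA2 quartile), score
stromal gene-set enrichment before and after that correction, run the
compartment-deconvolved contrast, and fit the left-truncated survival
model on the dichotomised staining marker. Every stochastic step derives
its seed from the single config seed, so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as slio
from .clinical import (CoxFit, chi_squared, cox_fit, dichotomise_staining,
                       fisher_exact, km_estimate, median_dichotomise,
                       two_sample_t, wilcoxon_rank_sum)
from .diffexpr import (CompartmentDeResult, DeResult, EnrichmentResult,
                       contrast_groups, cssam_de, de_test, gsea_enrichment,
                       top_k, ward_cluster)
from .segmentation import SegmentationConfig, segment_slide
from .signature import (GeneSet, calibrate_and_predict, jonckheere_terpstra,
                        quantile_bin, rank_stromal_genes, signature_score)
from .simulate import (CohortConfig, ImageConfig, SurvivalConfig,
                       generate_clinical, generate_he_image, generate_staining,
                       generate_cohort_expression)

__all__ = ["PipelineConfig", "AnalysisReport", "run_full_analysis",
           "write_bundle", "load_bundle", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the full replay, with one master seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    n_images: int = 20              # samples that get an H&E tile
    contrast_gene: str = "PTEN"
    quartiles: int = 4
    prior_df: float = 4.0
    n_top: int = 50
    gsea_perm: int = 1000
    cssam_perm: int = 200
    use_entry: bool = True
    adjusters: tuple = ("age", "stage", "grade", "site")


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


@dataclass
class AnalysisReport:
    """Everything the replay computes, traceable to the config seed."""

    config: PipelineConfig
    fractions_measured: pd.DataFrame     # imaged samples: estimated vs true
    calibration: object
    fractions_predicted: pd.Series
    gene_ranking: pd.DataFrame
    de_all: DeResult
    de_acta2_low: DeResult
    top_genes: list
    cluster_order: list
    es_all: EnrichmentResult
    es_acta2_low: EnrichmentResult
    cssam: CompartmentDeResult
    staining: pd.Series
    clinical: pd.DataFrame
    cox: CoxFit
    km: dict
    association_tests: pd.DataFrame
    trend_test: tuple


def run_full_analysis(config: PipelineConfig | None = None) -> AnalysisReport:
    cfg = config or PipelineConfig()
    (seed_expr, seed_img, seed_stain, seed_clin, seed_gsea1, seed_gsea2,
     seed_cssam, seed_jt) = _child_seeds(cfg.seed, 8)

    # --- expression cohort and imaged subset -----------------------------
    expr, truth = generate_cohort_expression(cfg.cohort, seed_expr)
    imaged = list(expr.columns[:cfg.n_images])
    img_seeds = _child_seeds(seed_img, len(imaged))
    rows = []
    for sid, s in zip(imaged, img_seeds):
        target = float(truth.fractions[sid])
        rgb, _, _, achieved = generate_he_image(target, cfg.image, seed=s)
        seg = segment_slide(rgb, cfg.segmentation)
        rows.append({"image_id": sid, "stromal_fraction": seg.stromal_fraction,
                     "true_fraction": achieved,
                     "tissue_pixels": int(seg.tissue_mask.sum()),
                     "stroma_pixels": int(seg.stroma_mask.sum()),
                     "flags": ";".join(seg.flags)})
    measured = pd.DataFrame(rows).set_index("image_id")

    # --- signature calibration and gene ranking --------------------------
    stromal_set = GeneSet("stromal_signature", truth.signature_genes)
    scores = signature_score(expr, stromal_set, standardise=True)
    predicted, calibration = calibrate_and_predict(
        measured["stromal_fraction"].dropna(), scores)
    ranking_table = rank_stromal_genes(expr, predicted, stromal_set)

    # automated fractions vs ordinal "manual" bins of the generator truth
    bins, _ = quantile_bin(truth.fractions.loc[imaged].to_numpy(), 4)
    est = measured["stromal_fraction"].to_numpy(dtype=float)
    ok = np.isfinite(est)
    trend = jonckheere_terpstra(est[ok], bins[ok],
                                ordered_groups=np.unique(bins[ok]),
                                n_perm=10_000, seed=seed_jt)

    # --- PTEN-quartile DE, before and after ACTA2-low restriction --------
    low, high = contrast_groups(expr, cfg.contrast_gene, cfg.quartiles)
    de_all = de_test(expr, low, high, prior_df=cfg.prior_df)
    es_all = gsea_enrichment(de_all["t"], stromal_set, weight_exponent=0,
                             n_perm=cfg.gsea_perm, seed=seed_gsea1)

    acta2_bins, _ = quantile_bin(expr.loc["ACTA2"].to_numpy(), cfg.quartiles)
    acta2_low_samples = list(expr.columns[acta2_bins == 1])
    sub = expr[acta2_low_samples]
    low2, high2 = contrast_groups(sub, cfg.contrast_gene, cfg.quartiles)
    de_low = de_test(sub, low2, high2, prior_df=cfg.prior_df)
    es_low = gsea_enrichment(de_low["t"], stromal_set, weight_exponent=0,
                             n_perm=cfg.gsea_perm, seed=seed_gsea2)

    genes50 = top_k(de_all, min(cfg.n_top, len(expr)))
    order = ward_cluster(expr.loc[genes50])

    # --- compartment-deconvolved contrast on the quartile samples --------
    contrast_samples = low + high
    groups = pd.Series(["low"] * len(low) + ["high"] * len(high),
                       index=contrast_samples)
    frac_used = predicted.loc[contrast_samples].clip(1e-3, 1 - 1e-3)
    cssam = cssam_de(expr[contrast_samples], frac_used, groups,
                     n_perm=cfg.cssam_perm, seed=seed_cssam)

    # --- staining, survival and association tests ------------------------
    staining = generate_staining(truth.copy_state, seed=seed_stain)
    marker = dichotomise_staining(staining)
    clinical = generate_clinical(marker == "reduced", cfg.survival, seed=seed_clin)
    clinical["pten_reduced"] = (marker == "reduced").astype(int).loc[clinical.index]
    cox = cox_fit(clinical, ["pten_reduced", *cfg.adjusters],
                  use_entry=cfg.use_entry)
    km = km_estimate(clinical, "pten_reduced", use_entry=cfg.use_entry)

    tests = []
    cs_tab = pd.crosstab(staining, truth.copy_state)
    p_fisher, _ = fisher_exact(cs_tab.to_numpy(), n_mc=20_000, seed=seed_stain)
    tests.append(("staining_vs_copy_state", "fisher_mc", p_fisher))
    pten = expr.loc["PTEN"]
    dip = pten[truth.copy_state == "diploid"]
    het = pten[truth.copy_state == "hetloss"]
    if len(dip) >= 2 and len(het) >= 2:
        t_stat, _, p_t = two_sample_t(dip, het)
        tests.append(("pten_diploid_vs_hetloss", "t", p_t))
        _, p_w = wilcoxon_rank_sum(dip, het)
        tests.append(("pten_diploid_vs_hetloss", "wilcoxon", p_w))
    ar_groups = median_dichotomise(expr.loc["AR"])
    pten_groups = median_dichotomise(pten)
    _, _, p_chi = chi_squared(pd.crosstab(ar_groups, pten_groups).to_numpy())
    tests.append(("ar_vs_pten_median", "chi_squared", p_chi))
    assoc = pd.DataFrame(tests, columns=["comparison", "test", "p"])

    return AnalysisReport(
        config=cfg, fractions_measured=measured, calibration=calibration,
        fractions_predicted=predicted, gene_ranking=ranking_table,
        de_all=de_all, de_acta2_low=de_low, top_genes=genes50,
        cluster_order=order.leaf_order, es_all=es_all, es_acta2_low=es_low,
        cssam=cssam, staining=staining, clinical=clinical, cox=cox, km=km,
        association_tests=assoc, trend_test=trend)


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write the report as reviewable TSV/JSON/PNG files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slio.write_fractions(report.fractions_measured, out / "fractions_measured.tsv")
    report.fractions_predicted.to_frame().to_csv(out / "fractions_predicted.tsv",
                                                 sep="\t")
    report.gene_ranking.to_csv(out / "gene_ranking.tsv", sep="\t")
    report.de_all.table.to_csv(out / "de_all.tsv", sep="\t")
    report.de_acta2_low.table.to_csv(out / "de_acta2_low.tsv", sep="\t")
    report.cssam.table.join(report.cssam.fdr.add_prefix("fdr_")) \
        .to_csv(out / "cssam.tsv", sep="\t")
    report.clinical.to_csv(out / "clinical.csv")
    report.association_tests.to_csv(out / "association_tests.tsv", sep="\t",
                                    index=False)
    slio.write_json({
        "seed": report.config.seed,
        "calibration": vars(report.calibration),
        "es_all": {"es": report.es_all.es, "p": report.es_all.p},
        "es_acta2_low": {"es": report.es_acta2_low.es, "p": report.es_acta2_low.p},
        "trend_test": {"J": report.trend_test[0], "p": report.trend_test[1]},
        "top_genes": report.top_genes,
        "cox": {k: v.to_dict() for k, v in report.cox.summary().items()},
        "cox_n": report.cox.n, "cox_events": report.cox.events,
    }, out / "report.json")
    _plot_heatmap(report, out / "heatmap.png")
    _plot_km(report, out / "km.png")


def _plot_heatmap(report, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    expr_top = report.de_all.table.loc[report.top_genes]
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(expr_top[["diff", "t"]].to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(report.top_genes)))
    ax.set_yticklabels(report.top_genes, fontsize=4)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["diff", "t"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_km(report, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    for label, curve in report.km.items():
        ax.step(curve.times, curve.survival, where="post",
                label=f"{label} (n={curve.n}, events={curve.events})")
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_bundle(out_dir, seed: int = 0,
                 cohort: CohortConfig | None = None,
                 image: ImageConfig | None = None,
                 survival: SurvivalConfig | None = None,
                 n_images: int = 20) -> Path:
    """Write a self-contained synthetic cohort directory.

    Layout: ``images/``, ``expression.tsv``, ``fractions_truth.tsv``,
    ``clinical.csv``, ``staining.tsv``, ``genesets.gmt``, ``truth.json``,
    ``config.yaml``.
    """
    import yaml

    cohort = cohort or CohortConfig()
    image = image or ImageConfig()
    survival = survival or SurvivalConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    seed_expr, seed_img, seed_stain, seed_clin = _child_seeds(seed, 4)

    expr, truth = generate_cohort_expression(cohort, seed_expr)
    slio.write_expression(expr, out / "expression.tsv")

    imaged = list(expr.columns[:n_images])
    img_seeds = _child_seeds(seed_img, len(imaged))
    rows = []
    for sid, s in zip(imaged, img_seeds):
        rgb, tissue, stroma, achieved = generate_he_image(
            float(truth.fractions[sid]), image, seed=s)
        slio.write_image(rgb, out / "images" / f"{sid}.png")
        rows.append({"image_id": sid, "stromal_fraction": achieved,
                     "tissue_pixels": int(tissue.sum()),
                     "stroma_pixels": int(stroma.sum()), "flags": ""})
    slio.write_fractions(pd.DataFrame(rows).set_index("image_id"),
                         out / "fractions_truth.tsv")

    staining = generate_staining(truth.copy_state, seed=seed_stain)
    staining.to_frame().join(truth.copy_state.rename("copy_state")) \
        .to_csv(out / "staining.tsv", sep="\t", index_label="sample_id")
    marker = dichotomise_staining(staining)
    clinical = generate_clinical(marker == "reduced", survival, seed=seed_clin)
    slio.write_clinical(clinical, out / "clinical.csv")
    slio.write_gmt([GeneSet("stromal_signature", truth.signature_genes)],
                   out / "genesets.gmt")
    slio.write_json({"seed": seed,
                     "fractions": truth.fractions.to_dict(),
                     "copy_state": truth.copy_state.to_dict(),
                     "rho": truth.rho, "noise_sd": truth.noise_sd},
                    out / "truth.json")
    (out / "config.yaml").write_text(yaml.safe_dump({
        "seed": seed, "n_images": n_images,
        "cohort": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cohort).items()},
        "survival": vars(survival),
        "image": {k: v for k, v in vars(image).items() if k != "basis"},
    }))
    return out


def load_bundle(bundle_dir) -> dict:
    """Read a cohort bundle back; raises with context on schema violations."""
    d = Path(bundle_dir)
    out = {
        "expression": slio.read_expression(d / "expression.tsv"),
        "fractions": slio.read_fractions(d / "fractions_truth.tsv"),
        "clinical": slio.read_clinical(d / "clinical.csv"),
        "gene_sets": slio.read_gmt(d / "genesets.gmt"),
        "staining": pd.read_csv(d / "staining.tsv", sep="\t", index_col=0),
        "truth": slio.read_json(d / "truth.json"),
    }
    images = {}
    for p in sorted((d / "images").glob("*.png")):
        images[p.stem] = slio.read_image(p)
    out["images"] = images
    return out
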