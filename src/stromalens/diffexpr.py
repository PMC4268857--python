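"""Stroma-corrected differential expression and enrichment.

The central analysis contrasts the top and bottom quartiles of a gene's
expression (PTEN in the motivating study) with a moderated two-sample t
statistic, controls the FDR with Benjamini-Hochberg, scores a stromal gene
set with the classic GSEA running sum, and checks the contrast with a
compartment-deconvolved (csSAM-style) model that regresses each gene on the
per-sample stroma/tumour mixing fractions. Running the same contrast inside
the lowest ACTA2 quartile removes most of the stromal confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .signature import GeneSet, quantile_bin

__all__ = [
    "DeResult",
    "EnrichmentResult",
    "CompartmentDeResult",
    "ClusterOrdering",
    "contrast_groups",
    "de_test",
    "benjamini_hochberg",
    "top_k",
    "ward_cluster",
    "gsea_enrichment",
    "cssam_de",
]


def contrast_groups(expr: pd.DataFrame, gene_id: str,
                    q: int = 4) -> tuple[list[str], list[str]]:
    """Bottom- and top-quantile sample ids by one gene's expression.

    Default quartiles: returns ``(low, high)`` sample id lists for the
    first and last bins of :func:`~stromalens.signature.quantile_bin`.
    """
    if gene_id not in expr.index:
        raise KeyError(f"gene {gene_id!r} not in the expression matrix")
    values = expr.loc[gene_id].to_numpy(dtype=float)
    if expr.shape[1] < 2 * q:
        raise ValueError(f"need at least {2 * q} samples for a {q}-quantile contrast")
    labels, _ = quantile_bin(values, q)
    cols = np.asarray(expr.columns)
    return list(cols[labels == 1]), list(cols[labels == q])


@dataclass
class DeResult:
    """Per-gene differential expression table with BH-adjusted q-values."""

    table: pd.DataFrame  # columns: diff, t, p, q
    n_a: int
    n_b: int
    prior_df: float

    def __getitem__(self, col):
        return self.table[col]


def de_test(expr: pd.DataFrame, group_a, group_b,
            prior_df: float = 4.0) -> DeResult:
    """Moderated two-sample t test per gene (group B minus group A).

    Gene-wise pooled variances are shrunk toward the cohort-wide mean
    variance s0^2 with ``prior_df`` pseudo-observations:
    ``s_mod^2 = (prior_df * s0^2 + df * s^2) / (prior_df + df)``, and the t
    statistic on the moderated standard error is referred to a t
    distribution with ``df + prior_df`` degrees of freedom. ``prior_df=0``
    recovers the classical pooled two-sample t exactly.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if prior_df < 0:
        raise ValueError("prior_df must be >= 0")
    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1))
    s2 = ss / df
    s0_sq = float(s2.mean())
    s2_mod = (prior_df * s0_sq + df * s2) / (prior_df + df)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    q = benjamini_hochberg(p)
    table = pd.DataFrame({"diff": diff, "t": t, "p": p, "q": q}, index=expr.index)
    return DeResult(table, na, nb, prior_df)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def top_k(de: DeResult, k: int = 50) -> list[str]:
    """The k most significant genes: ascending p, ties by |diff| descending,
    then gene id."""
    tab = de.table
    if k > len(tab):
        raise ValueError(f"k={k} exceeds the {len(tab)} tested genes")
    order = tab.assign(_absdiff=-tab["diff"].abs(), _gene=tab.index) \
        .sort_values(["p", "_absdiff", "_gene"], kind="mergesort")
    return list(order.index[:k])


@dataclass
class ClusterOrdering:
    """Ward linkage tree and deterministic leaf order for heat-map display."""

    linkage: np.ndarray
    leaf_order: list
    labels: list


def ward_cluster(matrix: pd.DataFrame) -> ClusterOrdering:
    """Agglomerative Ward clustering of rows on Euclidean distances."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    labels = list(matrix.index) if isinstance(matrix, pd.DataFrame) \
        else list(range(values.shape[0]))
    link = hierarchy.linkage(pdist(values, metric="euclidean"), method="ward")
    leaves = hierarchy.leaves_list(link)
    return ClusterOrdering(link, [labels[i] for i in leaves], labels)


@dataclass
class EnrichmentResult:
    """GSEA running-sum enrichment of one gene set in one ranking."""

    es: float
    running_sum: np.ndarray   # length N + 1, starts and ends at 0
    p: float | None
    set_size: int
    ranking_size: int


def _running_sum(is_hit: np.ndarray, scores: np.ndarray, weight: int) -> np.ndarray:
    n = is_hit.size
    m = int(is_hit.sum())
    if weight == 0:
        hit_inc = np.full(n, 1.0 / m)
    else:
        w = np.abs(scores) ** weight
        total = w[is_hit].sum()
        hit_inc = np.where(total > 0, w / total, 1.0 / m)
    steps = np.where(is_hit, hit_inc, -1.0 / (n - m))
    return np.concatenate([[0.0], np.cumsum(steps)])


def gsea_enrichment(ranking: pd.Series, gene_set: GeneSet,
                    weight_exponent: int = 0, n_perm: int = 1000,
                    seed: int | None = None) -> EnrichmentResult:
    """Classic GSEA enrichment score of a gene set in a ranked list.

    ``ranking`` maps gene id to ranking score (e.g. a signed t statistic)
    and is walked in descending score order; set hits increment the running
    sum (equally for ``weight_exponent=0``, |score|-weighted for 1), misses
    decrement 1/(N-m). ES is the signed maximal deviation from zero. The
    p-value (one-sided, for positive ES) comes from seeded permutations of
    the gene labels; ``n_perm=0`` skips it.
    """
    ranking = pd.Series(ranking).astype(float)
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    is_hit = order.index.isin(gene_set.genes)
    m = int(is_hit.sum())
    n = len(order)
    if m == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranking")
    if m == n:
        raise ValueError("gene set covers the whole ranking")
    scores = order.to_numpy()

    def _es(hits):
        rs = _running_sum(hits, scores, weight_exponent)
        return rs, rs[np.argmax(np.abs(rs))]

    rs, es = _es(is_hit)
    p = None
    if n_perm > 0:
        if seed is None:
            raise ValueError("a seed is required for the permutation p-value")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(is_hit)
            if _es(perm)[1] >= es:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return EnrichmentResult(float(es), rs, p, m, n)


@dataclass
class CompartmentDeResult:
    """Compartment-specific (stroma vs tumour) differential expression."""

    table: pd.DataFrame    # columns: stroma_diff, tumour_diff
    fdr: pd.DataFrame      # columns: stroma, tumour — per-gene plug-in FDR
    n_perm: int


def _fit_compartments(values: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Least-squares fit of genes x samples values on the (f, 1-f) design.

    Returns (2, n_genes): row 0 stroma, row 1 tumour compartment expression.
    """
    design = np.column_stack([fractions, 1.0 - fractions])
    coef, _, rank, _ = np.linalg.lstsq(design, values.T, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design: fractions constant within a group")
    return coef


def cssam_de(expr: pd.DataFrame, fractions: pd.Series, groups: pd.Series,
             n_perm: int = 200, seed: int | None = None) -> CompartmentDeResult:
    """csSAM-style compartment-deconvolved differential expression.

    Within each of two groups, every gene's observed expression is
    regressed on the two-column design (stromal fraction, tumour fraction),
    yielding per-compartment expression estimates; the contrast is the
    between-group difference per compartment. Significance is a plug-in FDR
    from seeded group-label permutations: for each |difference| threshold
    (the observed values), the median permutation exceedance count over the
    observed count, per compartment.
    """
    fractions = pd.Series(fractions).astype(float)
    groups = pd.Series(groups)
    samples = expr.columns
    f = fractions.loc[samples].to_numpy()
    g = groups.loc[samples].to_numpy()
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("groups must be binary")
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("fractions must lie strictly in (0, 1)")
    masks = [g == lev for lev in levels]
    if any(m.sum() < 4 for m in masks):
        raise ValueError("each group needs at least 4 samples")
    values = expr.to_numpy(dtype=float)

    def compartment_diff(group_masks):
        fits = [_fit_compartments(values[:, m], f[m]) for m in group_masks]
        return fits[1] - fits[0]   # (2, n_genes): [stroma, tumour]

    obs = compartment_diff(masks)
    table = pd.DataFrame({"stroma_diff": obs[0], "tumour_diff": obs[1]},
                         index=expr.index)

    fdr = pd.DataFrame(np.ones((len(expr), 2)), index=expr.index,
                       columns=["stroma", "tumour"])
    if n_perm > 0:
        if seed is None:
            raise ValueError("a seed is required for the permutation FDR")
        rng = np.random.default_rng(seed)
        perm_abs = np.empty((n_perm, 2, len(expr)))
        for i in range(n_perm):
            perm = rng.permutation(g)
            pm = [perm == lev for lev in levels]
            try:
                perm_abs[i] = np.abs(compartment_diff(pm))
            except ValueError:   # rare rank-deficient shuffle
                perm_abs[i] = np.inf
        for ci, comp in enumerate(["stroma", "tumour"]):
            d = np.abs(obs[ci])
            d_sorted = np.sort(d)
            n_called = len(d) - np.searchsorted(d_sorted, d, side="left")
            perm_sorted = np.sort(perm_abs[:, ci, :], axis=1)
            # false calls at threshold d[j] in permutation i, via sorted counts
            counts = len(d) - np.stack(
                [np.searchsorted(perm_sorted[i], d, side="left")
                 for i in range(n_perm)])
            false_calls = np.median(counts, axis=0)
            est = np.where(n_called > 0, false_calls / n_called, 1.0)
            fdr[comp] = np.minimum(est, 1.0)
    return CompartmentDeResult(table, fdr, n_perm)
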