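"""Linking image-derived stromal fractions to expression profiles.

Stromal content estimated from H&E tiles is validated against expression by
scoring a stromal gene signature per sample, ranking individual genes by
their Pearson correlation with the image-derived fraction, and testing the
trend of automated fractions across ordinal manual bins with the
Jonckheere-Terpstra test. A simple least-squares calibration then predicts
stromal content for samples that lack images.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "signature_score",
    "pearson_correlation",
    "rank_stromal_genes",
    "jonckheere_terpstra",
    "quantile_bin",
    "calibrate_and_predict",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a published stromal signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(self.genes)
        if not genes:
            raise ValueError("gene set is empty")
        if len(set(genes)) != len(genes):
            raise ValueError("gene set contains duplicate ids")
        object.__setattr__(self, "genes", genes)

    def __len__(self):
        return len(self.genes)


def _check_expr(expr: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(expr, pd.DataFrame):
        raise TypeError("expression must be a genes x samples DataFrame")
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return expr


def signature_score(expr: pd.DataFrame, gene_set: GeneSet,
                    standardise: bool = True) -> pd.Series:
    """Per-sample signature score: mean expression over the set's genes.

    With ``standardise`` each gene is z-scored across samples before
    averaging, so highly expressed genes do not dominate; the raw-mean mode
    averages log2 values directly.
    """
    expr = _check_expr(expr)
    present = [g for g in gene_set.genes if g in expr.index]
    if not present:
        missing = list(gene_set.genes)[:10]
        raise KeyError(
            f"no genes of set {gene_set.name!r} in the matrix (missing e.g. {missing})")
    sub = expr.loc[present]
    if standardise:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        sd = sd.replace(0.0, np.nan)
        sub = sub.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return sub.mean(axis=0).rename(f"{gene_set.name}_score")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def rank_stromal_genes(expr: pd.DataFrame, fractions: pd.Series,
                       gene_set: GeneSet) -> pd.DataFrame:
    """Correlate each signature gene with the stromal fraction and rank.

    Returns a DataFrame indexed by gene with columns ``r``, ``p`` and
    ``rank`` (1 = most positively correlated), sorted descending by r.
    """
    expr = _check_expr(expr)
    fractions = pd.Series(fractions)
    common = expr.columns.intersection(fractions.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between expression and fractions")
    present = [g for g in gene_set.genes if g in expr.index]
    if not present:
        raise KeyError(f"no genes of set {gene_set.name!r} present in the matrix")
    f = fractions.loc[common].to_numpy(dtype=float)
    rows = []
    for g in present:
        x = expr.loc[g, common].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            r_val, p_val = np.nan, np.nan
        else:
            r_val, p_val = pearson_correlation(x, f)
        rows.append((g, r_val, p_val))
    table = pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")
    table = table.sort_values("r", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _jt_statistic(values: np.ndarray, group_index: list[np.ndarray]) -> float:
    j = 0.0
    for a, b in combinations(range(len(group_index)), 2):
        xa = values[group_index[a]][:, None]
        xb = values[group_index[b]][None, :]
        j += np.sum(xa < xb) + 0.5 * np.sum(xa == xb)
    return float(j)


def jonckheere_terpstra(values, group_labels, ordered_groups=None,
                        n_perm: int = 10_000, seed: int | None = None,
                        method: str = "permutation"):
    """Jonckheere-Terpstra trend test for ordered groups.

    J sums, over ordered group pairs (k < l), the Mann-Whitney count
    #{x_k < x_l} + 0.5 #{x_k = x_l}. The one-sided (increasing-trend)
    p-value is estimated by seeded label permutation, or by a normal
    approximation with tie-corrected variance (``method="normal"``).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    if ordered_groups is None:
        ordered_groups = np.unique(labels)
    groups = [np.flatnonzero(labels == g) for g in ordered_groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")

    j_obs = _jt_statistic(values, groups)
    sizes = np.array([len(g) for g in groups])
    n = sizes.sum()

    if method == "normal":
        # tie-corrected null variance (Lehmann)
        _, tie_counts = np.unique(values, return_counts=True)
        t = tie_counts
        mean_j = (n * n - np.sum(sizes**2)) / 4.0
        term1 = (n * (n - 1) * (2 * n + 5)
                 - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
                 - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
        term2 = (np.sum(sizes * (sizes - 1) * (sizes - 2))
                 * np.sum(t * (t - 1) * (t - 2))) / (36.0 * n * (n - 1) * (n - 2))
        term3 = (np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1))) \
            / (8.0 * n * (n - 1))
        var_j = term1 + term2 + term3
        if var_j <= 0:
            return j_obs, 1.0
        z = (j_obs - mean_j) / np.sqrt(var_j)
        return j_obs, float(stats.norm.sf(z))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        perm_groups = [np.arange(starts[i], starts[i + 1]) for i in range(len(sizes))]
        if _jt_statistic(perm, perm_groups) >= j_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return j_obs, float(p)


def quantile_bin(values, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each value to one of q empirical-quantile bins (1..q).

    Type-7 quantiles; a value equal to a boundary goes to the lower bin.
    Returns ``(labels, boundaries)`` with q - 1 interior boundaries.
    """
    values = np.asarray(values, dtype=float)
    if q < 2:
        raise ValueError("q must be >= 2")
    if values.size < q:
        raise ValueError(f"need at least q={q} values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical: quantiles degenerate")
    boundaries = np.quantile(values, np.arange(1, q) / q)  # type-7 default
    # side="left" sends a value equal to a boundary to the lower bin
    labels = 1 + np.searchsorted(boundaries, values, side="left")
    return labels.astype(int), boundaries


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r: float


def calibrate_and_predict(fractions_scored: pd.Series,
                          scores_all: pd.Series) -> tuple[pd.Series, CalibrationFit]:
    """Predict stromal fractions from signature scores by OLS calibration.

    A least-squares line of image-derived fraction on signature score is
    fit on the samples that have both, then applied to every scored sample;
    predictions are clipped to [0, 1]. Returns the predictions and the fit
    diagnostics (slope, intercept, Pearson r on the calibration set).
    """
    fractions_scored = pd.Series(fractions_scored).dropna()
    scores_all = pd.Series(scores_all)
    common = fractions_scored.index.intersection(scores_all.index)
    if len(common) < 10:
        raise ValueError("need at least 10 samples with both fraction and score")
    x = scores_all.loc[common].to_numpy(dtype=float)
    y = fractions_scored.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant scores: calibration undefined")
    fit = stats.linregress(x, y)
    pred = fit.intercept + fit.slope * scores_all.to_numpy(dtype=float)
    pred = np.clip(pred, 0.0, 1.0)
    return (pd.Series(pred, index=scores_all.index, name="predicted_fraction"),
            CalibrationFit(float(fit.slope), float(fit.intercept), float(fit.rvalue)))
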