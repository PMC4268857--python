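"""Survival and association statistics for marker-stratified cohorts.

Staining categories (negative / weak positive / heterogeneous / positive)
are dichotomised into reduced vs retained marker expression; survival is
modelled with Kaplan-Meier curves and a Cox proportional hazards model that
supports left truncation (delayed entry): a subject contributes to the risk
set at time t only when entry < t <= exit, so deaths occurring before study
entry do not bias the hazard comparison. Contingency and rank tests
(Fisher, chi-squared, Wilcoxon, t) round out the toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "STAINING_CATEGORIES",
    "REDUCED_CATEGORIES",
    "CoxFit",
    "KmCurve",
    "dichotomise_staining",
    "km_estimate",
    "cox_fit",
    "build_design",
    "fisher_exact",
    "chi_squared",
    "wilcoxon_rank_sum",
    "two_sample_t",
    "median_dichotomise",
]

STAINING_CATEGORIES = ("negative", "weak_positive", "heterogeneous", "positive")
#: Categories counted as reduced marker expression (vs retained "positive").
REDUCED_CATEGORIES = frozenset({"negative", "weak_positive", "heterogeneous"})


def dichotomise_staining(categories) -> pd.Series:
    """Collapse staining categories to ``reduced`` vs ``retained``.

    Negative, weak-positive and heterogeneous staining all count as reduced
    expression; only uniformly positive staining is retained.
    """
    cats = pd.Series(categories)
    if cats.empty:
        raise ValueError("no staining categories supplied")
    unknown = set(cats) - set(STAINING_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown staining categories: {sorted(unknown)}")
    return cats.map(lambda c: "reduced" if c in REDUCED_CATEGORIES else "retained")


def _check_times(entry, exit_, event):
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event)
    if np.any(entry < 0):
        raise ValueError("negative entry times")
    if np.any(exit_ < entry):
        raise ValueError("exit_time earlier than entry_time")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return entry, exit_, event.astype(int)


@dataclass
class KmCurve:
    """Product-limit survival estimate for one group."""

    group: object
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    events: int


def km_estimate(table: pd.DataFrame, group_col: str | None = None,
                use_entry: bool = True, entry_col: str = "entry_time",
                exit_col: str = "exit_time", event_col: str = "event") -> dict:
    """Kaplan-Meier curves per group, optionally with delayed entry.

    With ``use_entry`` the risk set at time t is {entry < t <= exit}, so
    subjects are not counted at risk before they join the study.
    """
    entry, exit_, event = _check_times(table[entry_col] if entry_col in table
                                       else np.zeros(len(table)),
                                       table[exit_col], table[event_col])
    groups = table[group_col] if group_col else pd.Series(["all"] * len(table),
                                                          index=table.index)
    curves = {}
    for level in pd.unique(groups):
        m = (groups == level).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(exit_[m], event_observed=event[m],
                entry=entry[m] if use_entry else None)
        tab = kmf.event_table
        curves[level] = KmCurve(
            group=level,
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            at_risk=tab["at_risk"].to_numpy(dtype=float),
            n=int(m.sum()),
            events=int(event[m].sum()),
        )
    return curves


@dataclass
class CoxFit:
    """Fitted Cox proportional hazards model (Breslow ties, Wald inference)."""

    coef: pd.Series
    se: pd.Series
    hazard_ratio: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    log_likelihood: float
    n: int
    events: int
    n_iter: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "HR": self.hazard_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        })


def build_design(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design matrix: ordinal/numeric columns as-is, categorical
    (object) columns expanded into treatment-coded dummies."""
    cols = []
    for cov in covariates:
        col = table[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(cov))
    return pd.concat(cols, axis=1)


def _breslow_loglik(beta, x, entry, exit_, event, use_entry):
    """Breslow partial log-likelihood plus gradient and Hessian."""
    eta = x @ beta
    eta = eta - eta.max()       # scale-invariant: stabilises exp
    w = np.exp(eta)
    event_times = np.unique(exit_[event == 1])
    if use_entry:
        at_risk = (entry[None, :] < event_times[:, None]) & \
            (exit_[None, :] >= event_times[:, None])
    else:
        at_risk = exit_[None, :] >= event_times[:, None]
    is_event_at = (exit_[None, :] == event_times[:, None]) & (event[None, :] == 1)
    d = is_event_at.sum(axis=1).astype(float)

    s0 = at_risk @ w
    s1 = (at_risk * w) @ x
    xxw = w[:, None, None] * x[:, :, None] * x[:, None, :]
    s2 = np.tensordot(at_risk.astype(float), xxw, axes=1)

    loglik = float((eta * event).sum() - (d * np.log(s0)).sum())
    mean = s1 / s0[:, None]
    grad = (x * event[:, None]).sum(axis=0) - (d[:, None] * mean).sum(axis=0)
    hess = -np.einsum("k,kij->ij", d, s2 / s0[:, None, None]) \
        + np.einsum("k,ki,kj->ij", d, mean, mean)
    return loglik, grad, hess


def cox_fit(table: pd.DataFrame, covariates, use_entry: bool = True,
            entry_col: str = "entry_time", exit_col: str = "exit_time",
            event_col: str = "event", tol: float = 1e-8,
            max_iter: int = 50) -> CoxFit:
    """Cox proportional hazards regression with optional left truncation.

    Newton-Raphson maximisation of the Breslow partial likelihood, with
    delayed-entry risk sets when ``use_entry``. ``covariates`` may be
    column names of ``table`` (categoricals dummy-coded via
    :func:`build_design`) or a ready numeric design matrix. Wald 95%
    intervals ``exp(beta +/- 1.96 se)``; a ``separation-suspected`` flag is
    raised when a coefficient diverges.
    """
    entry, exit_, event = _check_times(
        table[entry_col] if (use_entry and entry_col in table)
        else np.zeros(len(table)), table[exit_col], table[event_col])
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    design = covariates if isinstance(covariates, pd.DataFrame) \
        else build_design(table, covariates)
    names = list(design.columns)
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError("collinear covariates")
    x = x - x.mean(axis=0)      # centring improves conditioning; beta unchanged

    beta = np.zeros(x.shape[1])
    trace = []
    flags = []
    for it in range(1, max_iter + 1):
        loglik, grad, hess = _breslow_loglik(beta, x, entry, exit_, event, use_entry)
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        trace.append((it, loglik, float(np.max(np.abs(step)))))
        if np.max(np.abs(beta)) > 15:
            flags.append("separation-suspected")
            break
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise RuntimeError(
            "Cox Newton-Raphson did not converge; trace: "
            + "; ".join(f"iter {i}: loglik={ll:.4f}, step={s:.2e}" for i, ll, s in trace))

    loglik, _, hess = _breslow_loglik(beta, x, entry, exit_, event, use_entry)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return CoxFit(
        coef=pd.Series(beta, idx), se=pd.Series(se, idx),
        hazard_ratio=pd.Series(np.exp(beta), idx),
        ci_low=pd.Series(np.exp(beta - 1.96 * se), idx),
        ci_high=pd.Series(np.exp(beta + 1.96 * se), idx),
        p=pd.Series(p, idx), log_likelihood=loglik, n=len(table),
        events=int(event.sum()), n_iter=it, flags=tuple(flags))


def _log_table_prob(table, row_m, col_m, n):
    return (gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact(table, n_mc: int = 100_000, seed: int | None = None):
    """Fisher's exact test for an R x C contingency table.

    2x2 tables use the exact hypergeometric two-sided test. Larger tables
    use seeded Monte-Carlo sampling with fixed margins (Patefield), where
    the p-value is the probability of a table no more likely than the
    observed one; returns ``(p, se)`` with a binomial standard error
    (se = None for the exact 2x2 path).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    table = np.round(table).astype(int)
    if table.sum() <= 0:
        raise ValueError("empty table")
    row_m, col_m = table.sum(axis=1), table.sum(axis=0)
    # degenerate margins leave a single possible table
    keep_r, keep_c = row_m > 0, col_m > 0
    if keep_r.sum() < 2 or keep_c.sum() < 2:
        return 1.0, None
    table = table[np.ix_(keep_r, keep_c)]
    row_m, col_m = table.sum(axis=1), table.sum(axis=0)

    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), None

    if seed is None:
        raise ValueError("a seed is required for the Monte-Carlo p-value")
    n = table.sum()
    log_p_obs = _log_table_prob(table, row_m, col_m, n)
    rng = np.random.default_rng(seed)
    samples = stats.random_table(row_m, col_m).rvs(n_mc, random_state=rng)
    log_p = (gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
             - gammaln(n + 1) - gammaln(samples + 1).sum(axis=(1, 2)))
    hits = int((log_p <= log_p_obs + 1e-9).sum())
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return float(p), se


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise ValueError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if np.any(expected < 5):
        warnings.warn("expected counts below 5: chi-squared approximation is poor",
                      stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def wilcoxon_rank_sum(x, y, exact_threshold: int = 25,
                      alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test; exact enumeration for small tie-free samples,
    otherwise a tie-corrected normal approximation.

    Returns ``(W, p)`` where W is the rank sum of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= exact_threshold and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2)   # U -> rank sum
    return w, float(res.pvalue)


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t test (pooled, or Welch-Satterthwaite). Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def median_dichotomise(values) -> pd.Series:
    """Split at the median: <= median is ``low``, above is ``high``."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if values.nunique() == 1:
        raise ValueError("all values identical: median split undefined")
    med = float(values.median())
    return values.map(lambda v: "low" if v <= med else "high")
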