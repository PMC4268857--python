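"""Staining dichotomy, Kaplan-Meier/Cox with left truncation, association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import stromalens as sl
from stromalens.clinical import cox_fit, _breslow_loglik


def _expand(counts):
    cats = []
    for cat, n in counts.items():
        cats.extend([cat] * n)
    return pd.Series(cats)


class TestDichotomiseStaining:
    def test_all_positive_all_retained(self):
        out = sl.dichotomise_staining(["positive"] * 5)
        assert (out == "retained").all()

    def test_if_cohort_counts(self):
        # staining-category counts of the first tissue-microarray cohort
        cats = _expand({"negative": 49, "weak_positive": 68,
                        "heterogeneous": 48, "positive": 49})
        out = sl.dichotomise_staining(cats)
        assert (out == "reduced").sum() == 165
        assert (out == "retained").sum() == 49

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            sl.dichotomise_staining([])
        with pytest.raises(ValueError):
            sl.dichotomise_staining(["positive", "strong"])


def _table(entry, exit_, event, **cov):
    d = {"entry_time": entry, "exit_time": exit_, "event": event}
    d.update(cov)
    return pd.DataFrame(d)


class TestKaplanMeier:
    def test_uncensored_product_limit_steps(self):
        t = _table([0, 0, 0], [1, 2, 3], [1, 1, 1])
        curve = sl.km_estimate(t)["all"]
        s = dict(zip(curve.times, curve.survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        t = _table([0, 0], [5, 8], [0, 0])
        curve = sl.km_estimate(t)["all"]
        assert np.allclose(curve.survival, 1.0)

    def test_delayed_entry_shrinks_first_risk_set(self):
        # C enters after A's death: S(5) = 1 - 1/2, not 1 - 1/3
        t = _table([0, 0, 6], [5, 10, 12], [1, 1, 1])
        curve = sl.km_estimate(t, use_entry=True)["all"]
        s = dict(zip(curve.times, curve.survival))
        assert s[5.0] == pytest.approx(1 / 2)
        naive = sl.km_estimate(t, use_entry=False)["all"]
        s0 = dict(zip(naive.times, naive.survival))
        assert s0[5.0] == pytest.approx(2 / 3)

    def test_entry_zero_equals_no_entry(self, rng):
        n = 40
        t = _table(np.zeros(n), rng.exponential(50, n),
                   rng.integers(0, 2, n), group=rng.integers(0, 2, n))
        a = sl.km_estimate(t, "group", use_entry=True)
        b = sl.km_estimate(t, "group", use_entry=False)
        for g in a:
            assert np.allclose(a[g].survival, b[g].survival)

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError):
            sl.km_estimate(_table([5.0], [2.0], [1]))

    def test_survival_monotone_from_one(self, rng):
        t = _table(rng.uniform(0, 10, 50), 10 + rng.exponential(40, 50),
                   rng.integers(0, 2, 50))
        curve = sl.km_estimate(t)["all"]
        assert curve.survival[0] <= 1.0 + 1e-12
        assert np.all(np.diff(curve.survival) <= 1e-12)


def _grid_beta(table, use_entry, lo=-3, hi=3, n=12001):
    """Brute-force maximiser of the Breslow partial likelihood on a grid."""
    x = table[["x"]].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    entry = table["entry_time"].to_numpy(dtype=float)
    exit_ = table["exit_time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    grid = np.linspace(lo, hi, n)
    lls = [_breslow_loglik(np.array([b]), x, entry, exit_, event, use_entry)[0]
           for b in grid]
    return grid[int(np.argmax(lls))]


class TestCox:
    def test_two_identical_groups_give_null(self):
        base = _table([0, 0, 0, 0], [2, 4, 6, 8], [1, 1, 0, 1])
        t = pd.concat([base.assign(x=0.0), base.assign(x=1.0)],
                      ignore_index=True)
        fit = cox_fit(t, ["x"])
        assert abs(fit.coef["x"]) < 1e-6
        assert fit.hazard_ratio["x"] == pytest.approx(1.0, abs=1e-5)

    def test_matches_grid_search_oracle(self):
        t = _table([0, 0, 1, 0, 2, 0, 1, 0],
                   [3, 5, 6, 7, 8, 9, 11, 14],
                   [1, 1, 1, 0, 1, 1, 0, 1],
                   x=[1, 0, 1, 1, 0, 1, 0, 0])
        fit = cox_fit(t, ["x"], use_entry=True)
        assert fit.coef["x"] == pytest.approx(_grid_beta(t, True), abs=1e-3)
        fit0 = cox_fit(t, ["x"], use_entry=False)
        assert fit0.coef["x"] == pytest.approx(_grid_beta(t, False), abs=1e-3)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        # Breslow == Efron without ties, so lifelines is an exact cross-check
        from lifelines import CoxPHFitter
        n = 150
        x = rng.normal(size=n)
        t = _table(rng.uniform(0, 5, n),
                   5 + rng.exponential(30 * np.exp(-0.5 * x)),
                   np.ones(n, dtype=int), x=x)
        fit = cox_fit(t, ["x"], use_entry=True)
        cph = CoxPHFitter()
        cph.fit(t, duration_col="exit_time", event_col="event",
                entry_col="entry_time", formula="x")
        assert fit.coef["x"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se["x"] == pytest.approx(
            cph.standard_errors_["x"], rel=1e-4)

    def test_wald_interval_brackets_hazard_ratio(self, rng):
        red = pd.Series(rng.random(400) < 0.5)
        clin = sl.generate_clinical(red, seed=4)
        fit = cox_fit(clin, ["pten_reduced"])
        assert fit.ci_low["pten_reduced"] <= fit.hazard_ratio["pten_reduced"] \
            <= fit.ci_high["pten_reduced"]
        assert fit.hazard_ratio["pten_reduced"] == pytest.approx(
            np.exp(fit.coef["pten_reduced"]))

    def test_left_truncation_matters(self):
        # with uniform entry and exponential hazards, ignoring delayed entry
        # inflates the estimated effect; the delayed-entry fit stays unbiased
        red = pd.Series(np.random.default_rng(3).random(4000) < 0.5)
        cfg = sl.SurvivalConfig(entry_max=120.0, baseline_rate=0.02)
        clin = sl.generate_clinical(red, cfg, seed=9)
        beta_t = cox_fit(clin, ["pten_reduced"], use_entry=True).coef["pten_reduced"]
        beta_n = cox_fit(clin, ["pten_reduced"], use_entry=False).coef["pten_reduced"]
        true_beta = np.log(cfg.hazard_ratio)
        assert beta_n - beta_t > 0.05
        assert abs(beta_t - true_beta) < abs(beta_n - true_beta)

    def test_collinear_covariates_rejected(self, rng):
        t = _table(np.zeros(20), rng.exponential(10, 20), np.ones(20, int),
                   x=np.arange(20.0))
        t["y"] = 2 * t["x"]
        with pytest.raises(ValueError):
            cox_fit(t, ["x", "y"])

    def test_too_few_events_rejected(self):
        t = _table([0, 0, 0], [1, 2, 3], [1, 0, 0], x=[0, 1, 0])
        with pytest.raises(ValueError):
            cox_fit(t, ["x"])


def _enumerate_fisher(table):
    """Exact R x C Fisher p by recursive enumeration of fixed-margin tables."""
    table = np.asarray(table, dtype=int)
    row_m, col_m = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()

    def log_prob(t):
        return (gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
                - gammaln(n + 1) - gammaln(np.asarray(t) + 1).sum())

    lp_obs = log_prob(table)
    total = 0.0
    hit = 0.0

    def rec(rows_left, col_rem, acc):
        nonlocal total, hit
        if len(rows_left) == 1:
            t = acc + [list(col_rem)]
            p = np.exp(log_prob(t))
            total += p
            if log_prob(t) <= lp_obs + 1e-9:
                hit += p
            return
        r = rows_left[0]

        def fill(j, rem_r, row_acc):
            if j == len(col_rem) - 1:
                if 0 <= rem_r <= col_rem[j]:
                    rec(rows_left[1:],
                        tuple(c - v for c, v in zip(col_rem, row_acc + [rem_r])),
                        acc + [row_acc + [rem_r]])
                return
            for v in range(min(rem_r, col_rem[j]) + 1):
                fill(j + 1, rem_r - v, row_acc + [v])

        fill(0, r, [])

    rec(list(row_m), tuple(col_m), [])
    assert abs(total - 1.0) < 1e-9
    return hit


class TestFisherExact:
    def test_two_by_two_hypergeometric(self):
        p, se = sl.fisher_exact([[3, 1], [1, 3]])
        assert se is None
        assert p == pytest.approx(34 / 70, abs=1e-10)

    def test_zero_margin_gives_one(self):
        p, _ = sl.fisher_exact([[0, 0], [3, 5]])
        assert p == 1.0

    def test_monte_carlo_close_to_enumeration(self):
        table = [[2, 1, 0, 1], [0, 2, 1, 0], [1, 0, 2, 0]]
        exact = _enumerate_fisher(table)
        p, se = sl.fisher_exact(table, n_mc=40_000, seed=0)
        assert abs(p - exact) <= 3 * se

    def test_type_one_error_controlled(self):
        from scipy.stats import random_table
        rng = np.random.default_rng(17)
        sampler = random_table([25, 35], [30, 30])
        tables = sampler.rvs(2000, random_state=rng)
        rejections = sum(sl.fisher_exact(t)[0] <= 0.05 for t in tables)
        assert rejections / 2000 <= 0.06

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sl.fisher_exact([[1, -2], [3, 4]])


class TestChiSquared:
    def test_proportional_table_is_independent(self):
        stat, df, p = sl.chi_squared([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        stat, df, p = sl.chi_squared([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-10)
        assert df == 1

    def test_degrees_of_freedom_contract(self, rng):
        stat, df, _ = sl.chi_squared(rng.integers(5, 30, (4, 3)))
        assert df == 6

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sl.chi_squared([[0, 0], [1, 2]])


class TestWilcoxon:
    def test_identical_samples_null(self):
        _, p = sl.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_small_sample_exact_enumeration(self):
        _, p = sl.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0], alternative="less")
        assert p == pytest.approx(1 / 6)

    @pytest.mark.parametrize("nx,ny", [(3, 4), (4, 4)])
    def test_matches_exhaustive_enumeration(self, nx, ny, rng):
        from itertools import combinations
        x = rng.normal(size=nx)
        y = rng.normal(size=ny)
        w_obs, p = sl.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        stats_all = [ranks[list(c)].sum()
                     for c in combinations(range(nx + ny), nx)]
        stats_all = np.array(stats_all)
        mu = stats_all.mean()
        p_exact = np.mean(np.abs(stats_all - mu) >= abs(w_obs - mu) - 1e-9)
        assert p == pytest.approx(p_exact, abs=1e-9)


class TestTwoSampleT:
    def test_equal_samples_null(self):
        t, df, p = sl.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 2, size=10)
        t, df, p = sl.two_sample_t(x, y)
        sp2 = ((7 * x.var(ddof=1) + 9 * y.var(ddof=1)) / 16)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 8 + 1 / 10))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 16

    def test_welch_df_bounded(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 5, 12)
        _, df_w, _ = sl.two_sample_t(x, y, welch=True)
        assert df_w <= 20


class TestMedianDichotomise:
    def test_even_split(self):
        out = sl.median_dichotomise([1.0, 2.0, 3.0, 4.0])
        assert list(out) == ["low", "low", "high", "high"]

    def test_odd_n_median_goes_low(self):
        out = sl.median_dichotomise([1.0, 2.0, 3.0])
        assert list(out) == ["low", "low", "high"]

    def test_balanced_sizes_for_distinct_values(self, rng):
        out = sl.median_dichotomise(rng.normal(size=101))
        counts = out.value_counts()
        assert abs(counts["low"] - counts["high"]) <= 1

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            sl.median_dichotomise([2.0, 2.0, 2.0])
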