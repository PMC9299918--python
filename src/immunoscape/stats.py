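"""Contingency-table, rank-based and survival statistics.

The 2x2 machinery reproduces printed univariate results exactly: the odds
ratio is computed in the (exposure rows: no/yes; outcome columns:
reference/event) orientation with a Wald confidence interval on the log
scale, and Fisher's exact test sums hypergeometric probabilities no larger
than the observed table's, in exact rational arithmetic.  The
linear-by-linear (Mantel-Haenszel) trend statistic is M^2 = (N-1) r^2 with r
the Pearson correlation between row and column scores.  Rank tests, the
Benjamini-Hochberg adjustment and Kaplan-Meier / log-rank are delegated to
scipy, statsmodels and lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    method: str
    p_value: float
    statistic: float = math.nan
    estimate: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    warnings: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _check_2x2(table) -> tuple[int, int, int, int]:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b, c, d = (int(x) for x in t.ravel())
    return a, b, c, d


def odds_ratio(table, ci_level: float = 0.95) -> TestResult:
    """Odds ratio of the event for exposed vs unexposed, with Wald CI.

    Orientation: rows = exposure (no, yes), columns = outcome (reference,
    event); OR = (d/c)/(b/a) — identical to the exponentiated univariate
    logistic coefficient.  Zero cells give OR exactly 0 or inf with the
    corresponding CI bound undefined (no continuity correction).
    """
    a, b, c, d = _check_2x2(table)
    n = a + b + c + d
    if (a == 0 or b == 0) and (c == 0 or d == 0):
        raise ValueError("odds ratio undefined: zero row in both exposure groups")
    if a == 0 or d == 0:
        # a zero denominator-odds or zero event count among exposed -> OR 0
        return TestResult(
            "odds_ratio_wald", math.nan, estimate=0.0,
            ci_low=0.0, ci_high=math.nan, n=n,
        )
    if b == 0 or c == 0:
        return TestResult(
            "odds_ratio_wald", math.nan, estimate=math.inf,
            ci_low=math.nan, ci_high=math.inf, n=n,
        )
    est = (d / c) / (b / a)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    log_or = math.log(est)
    p = 2.0 * sps.norm.sf(abs(log_or) / se)
    return TestResult(
        "odds_ratio_wald",
        p_value=float(p),
        statistic=log_or / se,
        estimate=est,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        n=n,
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test by exact rational enumeration.

    p is the sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (standard, not mid-p).  Degenerate margins give p = 1.
    """
    a, b, c, d = _check_2x2(table)
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult("fisher_exact", 1.0, n=n,
                          warnings=["degenerate margins"] if n else [])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p = sum(pk for pk in probs.values() if pk <= p_obs)
    return TestResult("fisher_exact", float(p), statistic=float(p_obs), n=n)


def trend_test(table, col_scores=None, row_scores=None) -> TestResult:
    """Linear-by-linear (Mantel-Haenszel) association test for an r x k table.

    M^2 = (N - 1) r^2, with r the Pearson correlation between row and column
    scores over the N subjects; p from chi-square with 1 df.  Default scores
    are 1..r and 1..k.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    r_, k_ = t.shape
    u = np.asarray(row_scores if row_scores is not None else np.arange(1, r_ + 1), float)
    v = np.asarray(col_scores if col_scores is not None else np.arange(1, k_ + 1), float)
    N = t.sum()
    if N <= 1:
        raise ValueError("need at least 2 subjects")
    pu = t.sum(axis=1)
    pv = t.sum(axis=0)
    mu_u = (pu * u).sum() / N
    mu_v = (pv * v).sum() / N
    var_u = (pu * (u - mu_u) ** 2).sum() / N
    var_v = (pv * (v - mu_v) ** 2).sum() / N
    if var_u <= 0 or var_v <= 0:
        raise ValueError("zero variance in a margin")
    cov = (t * np.outer(u - mu_u, v - mu_v)).sum() / N
    r = cov / math.sqrt(var_u * var_v)
    m2 = (N - 1) * r * r
    p = float(sps.chi2.sf(m2, df=1))
    return TestResult(
        "linear_by_linear", p, statistic=float(m2), estimate=float(r), n=int(N)
    )


def _all_tied(values: np.ndarray) -> bool:
    return np.unique(values).size <= 1


def rank_sum(x, y, exact_limit: int = 20) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is at most
    ``exact_limit`` and there are no ties; midrank/normal approximation with
    tie correction otherwise.  All-tied data give p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    if _all_tied(pooled):
        return TestResult("rank_sum", 1.0, n=pooled.size, warnings=["all values tied"])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_limit and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        "rank_sum", float(res.pvalue), statistic=float(res.statistic),
        n=pooled.size, extras={"method_detail": method},
    )


def signed_rank(deltas, exact_limit: int = 20) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (standard convention); all-zero input
    gives p = 1 with a warning.
    """
    d = np.asarray(deltas, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing differences")
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult("signed_rank", 1.0, n=d.size, warnings=["all differences zero"])
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= exact_limit and not ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return TestResult(
        "signed_rank", float(res.pvalue), statistic=float(res.statistic),
        n=d.size, extras={"method_detail": method},
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(groups: dict) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis test with BH-adjusted pairwise rank-sum comparisons."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if _all_tied(pooled):
        overall = TestResult("kruskal_wallis", 1.0, n=pooled.size,
                             warnings=["all values tied"])
    else:
        res = sps.kruskal(*arrays)
        overall = TestResult(
            "kruskal_wallis", float(res.pvalue), statistic=float(res.statistic),
            n=pooled.size,
        )
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = rank_sum(arrays[i], arrays[j])
            rows.append({"group_a": names[i], "group_b": names[j], "p": r.p_value})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_bh"] = bh_adjust(pairwise["p"].to_numpy())
    return overall, pairwise


def km_logrank(times, events, group) -> tuple[pd.DataFrame, dict, TestResult | None]:
    """Kaplan-Meier curves per group, median survival, and the log-rank test.

    Median survival is the earliest time at which the product-limit estimate
    drops to 0.5 or below; a group whose curve never reaches 0.5 (e.g. no
    events) has an undefined median (nan).  The test is the two-group
    log-rank chi-square (multivariate form for more than two groups), or
    None for a single group.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    labels = pd.unique(group)

    curves = []
    medians = {}
    for g in labels:
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = g
        curves.append(sf)
        med = float(kmf.median_survival_time_)
        medians[g] = math.nan if math.isinf(med) else med

    if len(labels) < 2:
        test = None
    elif len(labels) == 2:
        sel = group == labels[0]
        r = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
        test = TestResult(
            "logrank", float(r.p_value), statistic=float(r.test_statistic),
            n=times.size,
        )
    else:
        r = multivariate_logrank_test(times, group, events)
        test = TestResult(
            "logrank_multivariate", float(r.p_value),
            statistic=float(r.test_statistic), n=times.size,
        )
    return pd.concat(curves, ignore_index=True), medians, test
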