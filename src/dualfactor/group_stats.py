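"""Group-comparison statistics: omnibus tests, effect sizes, moments.

The four status groups are compared on categorical variables with Pearson
chi-squared tests (switching to Fisher's exact test when any expected cell
count falls below 5) and on continuous variables with one-way ANOVA plus
Tukey–Kramer post-hoc comparisons.  Effect sizes are Cohen's h for
proportions and Cohen's d for means — the latter with the equal-weight
root-mean-square denominator sqrt((s1^2 + s2^2)/2), not the n-weighted
pooled SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "cohens_h",
    "cohens_d",
    "crosstab_test",
    "fisher_exact_rxc",
    "anova_tukey",
    "spearman_rho",
    "moments",
    "GroupComparison",
    "DistributionMoments",
    "compare_categorical",
    "compare_continuous",
]


@dataclass
class GroupComparison:
    variable: str
    test: str  # chi_squared | fisher_exact | anova
    statistic: float
    df: object  # int for chi2; (df1, df2) for ANOVA; None for Fisher
    p_value: float
    significant: bool | None
    pairwise: list  # (group_pair, effect size, adjusted p or None)


@dataclass(frozen=True)
class DistributionMoments:
    skewness: float
    excess_kurtosis: float


def cohens_h(p1: float, p2: float) -> float:
    """Cohen's effect size for two proportions: |2 asin sqrt(p1) - 2 asin sqrt(p2)|."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return abs(2 * math.asin(math.sqrt(p1)) - 2 * math.asin(math.sqrt(p2)))


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardised mean difference with denominator sqrt((sd1^2+sd2^2)/2).

    This equal-weight RMS denominator (not the n-weighted pooled SD) is the
    module's convention throughout.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)


def fisher_exact_rxc(table, max_total: int = 400, mc_samples: int = 20000) -> float:
    """Conditional p-value for an r x c table (probability ordering).

    For totals up to ``max_total``, enumerates every table with the
    observed margins and sums the multivariate-hypergeometric
    probabilities of tables whose probability does not exceed the observed
    one.  Larger tables fall back to Patefield Monte-Carlo sampling of
    tables with fixed margins (``mc_samples`` draws, fixed internal seed,
    so the result is deterministic), the same device R's exact test uses
    when full network enumeration is infeasible.
    """
    t = np.asarray(table, dtype=int)
    r, c = t.shape
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())

    from math import lgamma

    def lfact(k):
        return lgamma(k + 1)

    const = sum(lfact(x) for x in row) + sum(lfact(x) for x in col) - lfact(n)

    def logprob(cells):
        return const - sum(lfact(x) for x in cells)

    obs_lp = logprob(t.ravel())

    if n > max_total:
        sampler = stats.random_table(row, col, seed=np.random.default_rng(0))
        draws = sampler.rvs(mc_samples).reshape(mc_samples, -1)
        lfact_lut = np.array([lfact(k) for k in range(n + 1)])
        lps = const - lfact_lut[draws.astype(int)].sum(axis=1)
        hits = int((lps <= obs_lp + 1e-9).sum())
        return (hits + 1) / (mc_samples + 1)

    total_p = 0.0

    # enumerate row by row; within a row, cell by cell with feasibility bounds
    def rec_rows(row_idx, col_left, acc):
        nonlocal total_p
        if row_idx == r - 1:
            cells = acc + list(col_left)
            lp = logprob(cells)
            if lp <= obs_lp + 1e-9:
                total_p += math.exp(lp)
            return
        rest_rows = int(row[row_idx + 1:].sum())

        def rec_cells(j, left_in_row, col_rem, row_cells):
            if j == c - 1:
                if left_in_row <= col_rem[j] and rest_rows >= col_rem[j] - left_in_row >= 0:
                    new_rem = list(col_rem)
                    new_rem[j] -= left_in_row
                    rec_rows(row_idx + 1, new_rem, acc + row_cells + [left_in_row])
                return
            hi = min(left_in_row, col_rem[j])
            for v in range(hi + 1):
                new_rem = list(col_rem)
                new_rem[j] -= v
                rec_cells(j + 1, left_in_row - v, new_rem, row_cells + [v])

        rec_cells(0, int(row[row_idx]), col_left, [])

    rec_rows(0, list(col), [])
    return min(total_p, 1.0)


def crosstab_test(
    counts,
    variable: str = "",
    fisher_expected_threshold: float = 5.0,
    alpha: float | None = None,
) -> GroupComparison:
    """Test independence in an r x c contingency table.

    Pearson chi-squared (without continuity correction) with
    df = (r-1)(c-1); switches to Fisher's exact test when any expected
    count is below ``fisher_expected_threshold`` (2x2 via the
    hypergeometric; larger tables by exhaustive enumeration, feasible for
    the small totals where the switch occurs).
    """
    t = np.asarray(counts, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    use_fisher = (expected < fisher_expected_threshold).any()

    if use_fisher:
        if t.shape == (2, 2):
            _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        else:
            p = fisher_exact_rxc(t.astype(int))
        stat, df = math.nan, None
        test = "fisher_exact"
    else:
        chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
        stat, test = float(chi2), "chi_squared"

    return GroupComparison(
        variable=variable,
        test=test,
        statistic=stat,
        df=df,
        p_value=float(p),
        significant=None if alpha is None else bool(p < alpha),
        pairwise=[],
    )


def anova_tukey(values, groups, variable: str = "", alpha: float | None = None) -> GroupComparison:
    """One-way ANOVA with Tukey–Kramer post-hoc pairwise comparisons.

    Handles unequal group sizes (the Kramer correction is built into the
    studentised-range procedure).  Pairwise entries carry the Cohen's d
    magnitude (RMS denominator) alongside the Tukey-adjusted p-value.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = ~np.isnan(v)
    v, g = v[ok], g[ok]
    labels = list(dict.fromkeys(g.tolist()))
    samples = {lab: v[g == lab] for lab in labels}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")

    f_stat, p = stats.f_oneway(*[samples[lab] for lab in labels])
    k, n = len(labels), len(v)

    tukey = pairwise_tukeyhsd(v, g, alpha=0.05)
    idx_i, idx_j = tukey._multicomp.pairindices
    adj_p = {
        frozenset((tukey.groupsunique[i], tukey.groupsunique[j])): float(padj)
        for i, j, padj in zip(idx_i, idx_j, tukey.pvalues)
    }

    pairwise = []
    for g1, g2 in combinations(labels, 2):
        s1, s2 = samples[g1], samples[g2]
        d = cohens_d(s1.mean(), s1.std(ddof=1), s2.mean(), s2.std(ddof=1))
        pairwise.append(((g1, g2), d, adj_p.get(frozenset((g1, g2)))))

    return GroupComparison(
        variable=variable,
        test="anova",
        statistic=float(f_stat),
        df=(k - 1, n - k),
        p_value=float(p),
        significant=None if alpha is None else bool(p < alpha),
        pairwise=pairwise,
    )


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def moments(values) -> DistributionMoments:
    """Bias-adjusted skewness (G1) and excess kurtosis (G2).

    The adjusted Fisher–Pearson conventions of mainstream statistical
    packages; used to judge approximate normality before ANOVA.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 4:
        raise ValueError("need at least 4 values for adjusted kurtosis")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: moments undefined")
    return DistributionMoments(
        skewness=float(stats.skew(v, bias=False)),
        excess_kurtosis=float(stats.kurtosis(v, fisher=True, bias=False)),
    )


def _two_proportion_z(x1, n1, x2, n2) -> float:
    """Two-sided pooled two-proportion z-test p-value."""
    p_pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / se
    return 2 * stats.norm.sf(abs(z))


def compare_categorical(
    flags_by_group: dict,
    variable: str = "",
    alpha: float | None = None,
    fisher_expected_threshold: float = 5.0,
) -> GroupComparison:
    """Compare one binary variable across groups.

    ``flags_by_group`` maps group label -> boolean array.  Omnibus via
    :func:`crosstab_test` on the groups x {yes, no} table; pairwise
    column-proportion comparisons as Bonferroni-adjusted two-proportion
    z-tests (the convention of mainstream survey software), each pair also
    carrying its Cohen's h.
    """
    labels = list(flags_by_group)
    table = []
    for lab in labels:
        f = np.asarray(flags_by_group[lab], dtype=bool)
        table.append([int(f.sum()), int((~f).sum())])
    cmp = crosstab_test(
        np.asarray(table), variable=variable, alpha=alpha,
        fisher_expected_threshold=fisher_expected_threshold,
    )
    m = len(labels) * (len(labels) - 1) // 2
    pairwise = []
    for (i, g1), (j, g2) in combinations(enumerate(labels), 2):
        x1, n1 = table[i][0], sum(table[i])
        x2, n2 = table[j][0], sum(table[j])
        h = cohens_h(x1 / n1, x2 / n2)
        p_adj = min(1.0, _two_proportion_z(x1, n1, x2, n2) * m)
        pairwise.append(((g1, g2), h, p_adj))
    cmp.pairwise = pairwise
    return cmp


def compare_continuous(values, groups, variable: str = "", alpha: float | None = None) -> GroupComparison:
    """Compare one continuous variable across groups (ANOVA + Tukey + d)."""
    return anova_tukey(values, groups, variable=variable, alpha=alpha)
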