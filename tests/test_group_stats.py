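import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualfactor.group_stats import (
    anova_tukey,
    cohens_d,
    cohens_h,
    compare_categorical,
    crosstab_test,
    fisher_exact_rxc,
    moments,
    spearman_rho,
)

prop = st.floats(0.0, 1.0, allow_nan=False)


class TestEffectSizes:
    def test_cohens_h_published_gender_contrast(self):
        # girls in Troubled (190/255) vs Complete (244/663)
        assert round(cohens_h(190 / 255, 244 / 663), 2) == 0.78

    def test_cohens_h_published_stress_contrast(self):
        # stressed in Troubled (194/255) vs Complete (145/663)
        assert round(cohens_h(194 / 255, 145 / 663), 2) == 1.15

    def test_cohens_h_identity_and_range_check(self):
        assert cohens_h(0.37, 0.37) == 0.0
        with pytest.raises(ValueError):
            cohens_h(1.2, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(prop, prop)
    def test_cohens_h_symmetric_and_monotone(self, p1, p2):
        assert cohens_h(p1, p2) == pytest.approx(cohens_h(p2, p1))
        # strictly increasing in the arcsine gap
        gap = abs(math.asin(math.sqrt(p1)) - math.asin(math.sqrt(p2)))
        assert cohens_h(p1, p2) == pytest.approx(2 * gap)

    def test_cohens_d_published_resilience_contrast(self):
        # CYRM mean (SD): Complete 48.9 (5.6) vs Troubled 40.0 (7.1)
        assert round(cohens_d(48.9, 5.6, 40.0, 7.1), 2) == 1.39

    def test_cohens_d_published_sss_contrast(self):
        assert round(cohens_d(7.3, 1.5, 5.3, 2.1), 2) == 1.10

    def test_cohens_d_identity_and_validation(self):
        assert cohens_d(5.0, 1.0, 5.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 2.0, 1.0)


class TestCrosstab:
    def test_perfect_independence(self):
        r = crosstab_test([[10, 10], [10, 10]])
        assert r.test == "chi_squared"
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_chi_squared_matches_textbook_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = rng.integers(5, 40, size=(3, 4)).astype(float)
            r = crosstab_test(t, fisher_expected_threshold=0.0)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            chi2 = sum(
                (t[i, j] - row[i] * col[j] / n) ** 2 / (row[i] * col[j] / n)
                for i in range(3)
                for j in range(4)
            )
            assert r.statistic == pytest.approx(chi2, rel=1e-12)
            assert r.df == 6

    def test_small_table_switches_to_fisher(self):
        r = crosstab_test([[3, 1], [1, 3]])
        assert r.test == "fisher_exact"
        # exhaustive hypergeometric enumeration over tables with margins (4,4)/(4,4)
        probs = [stats.hypergeom.pmf(a, 8, 4, 4) for a in range(5)]
        p_obs = probs[3]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert r.p_value == pytest.approx(expected, rel=1e-9)

    def test_rxc_fisher_enumeration_agrees_with_2x2_hypergeometric(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t = rng.integers(0, 6, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            _, p_scipy = stats.fisher_exact(t)
            assert fisher_exact_rxc(t) == pytest.approx(p_scipy, abs=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            crosstab_test([[0, 0], [3, 4]])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        vals = [1.0, 2.0, 3.0] * 4
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3
        r = anova_tukey(vals, groups)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.df == (3, 8)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        r = anova_tukey(np.r_[x, y], ["x"] * 30 + ["y"] * 25)
        t, p_t = stats.ttest_ind(x, y)
        assert r.statistic == pytest.approx(t**2, rel=1e-10)
        assert r.p_value == pytest.approx(p_t, rel=1e-10)

    def test_tukey_flags_exactly_the_shifted_group(self):
        # one group shifted a full SD: power > 0.99 at n=200/group
        rng = np.random.default_rng(2024)
        k, n = 4, 200
        vals = np.concatenate(
            [rng.normal(1.0 if lab == 3 else 0.0, 1.0, n) for lab in range(k)]
        )
        groups = np.repeat([f"g{i}" for i in range(k)], n)
        r = anova_tukey(vals, groups)
        for (a, b), _, p_adj in r.pairwise:
            involves_shifted = "g3" in (a, b)
            assert (p_adj < 0.05) == involves_shifted

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, list(reversed(x))) == pytest.approx(-1.0)

    def test_tied_sample_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0, 3.0, 5.0]
        rx = stats.rankdata(x)  # mid-ranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMoments:
    def test_symmetric_sample_has_zero_skew(self):
        vals = [-2.0, 0.0, 2.0] * 5
        assert moments(vals).skewness == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_formulas_against_hand_oracle(self):
        v = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        n = len(v)
        m = v.mean()
        m2 = ((v - m) ** 2).mean()
        m3 = ((v - m) ** 3).mean()
        m4 = ((v - m) ** 4).mean()
        g1 = m3 / m2**1.5
        G1 = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        r = moments(v)
        assert r.skewness == pytest.approx(G1, abs=1e-12)
        assert r.excess_kurtosis == pytest.approx(G2, abs=1e-12)

    def test_normal_sample_has_near_zero_excess_kurtosis(self):
        v = np.random.default_rng(1).standard_normal(100_000)
        assert abs(moments(v).excess_kurtosis) < 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            moments([2.0, 2.0, 2.0, 2.0])


class TestCompareCategorical:
    def test_pairwise_effect_sizes_and_bonferroni(self):
        rng = np.random.default_rng(8)
        flags = {
            "C": rng.random(300) < 0.2,
            "V": rng.random(300) < 0.5,
            "T": rng.random(150) < 0.8,
        }
        r = compare_categorical(flags, variable="stressed")
        assert r.test == "chi_squared"
        assert len(r.pairwise) == 3
        for (a, b), h, p_adj in r.pairwise:
            p_a = flags[a].mean()
            p_b = flags[b].mean()
            assert h == pytest.approx(cohens_h(p_a, p_b))
            assert 0 <= p_adj <= 1
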