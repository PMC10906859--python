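import math

import numpy as np
import pandas as pd
import pytest

from dualfactor.inference import (
    SeparationError,
    ZeroCellError,
    bonferroni_threshold,
    fit_logistic,
    hosmer_lemeshow,
    nagelkerke_r2,
    odds_ratio_2x2,
    vif_screen,
)
from dualfactor.synthetic import simulate_logistic_outcome


class TestOddsRatio:
    @pytest.mark.parametrize(
        "a, b, c, d, expected",
        [
            (190, 244, 65, 419, 5.02),  # girls, Troubled vs Complete
            (463, 244, 407, 419, 1.95),  # girls, Vulnerable vs Complete
            (194, 145, 61, 518, 11.36),  # stressed, Troubled vs Complete
        ],
    )
    def test_published_contrasts(self, a, b, c, d, expected):
        or_, (lo, hi) = odds_ratio_2x2(a, b, c, d)
        assert round(or_, 2) == expected
        assert lo < or_ < hi

    def test_balanced_table_gives_unity(self):
        or_, _ = odds_ratio_2x2(7, 7, 7, 7)
        assert or_ == pytest.approx(1.0)

    def test_woolf_interval_formula(self):
        or_, (lo, hi) = odds_ratio_2x2(20, 30, 10, 40)
        se = math.sqrt(1 / 20 + 1 / 30 + 1 / 10 + 1 / 40)
        assert lo == pytest.approx(or_ * math.exp(-1.959963984540054 * se))
        assert hi == pytest.approx(or_ * math.exp(1.959963984540054 * se))

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(ZeroCellError):
            odds_ratio_2x2(0, 5, 3, 7)
        or_, _ = odds_ratio_2x2(0, 5, 3, 7, haldane=True)
        assert or_ == pytest.approx((0.5 * 7.5) / (5.5 * 3.5))


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == pytest.approx(0.0)

    def test_perfect_prediction_scores_one(self):
        assert nagelkerke_r2(-69.31, 0.0, 100) == pytest.approx(1.0)

    def test_hand_worked_small_dataset(self):
        # n=8, L0 = 8 * ln(1/2); model halves the deviance
        l0 = 8 * math.log(0.5)
        l1 = l0 / 2
        r2_cs = 1 - math.exp(2 * (l0 - l1) / 8)
        expected = r2_cs / (1 - math.exp(2 * l0 / 8))
        assert nagelkerke_r2(l0, l1, 8) == pytest.approx(expected, abs=1e-12)

    def test_worse_than_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-50.0, -60.0, 100)

    def test_monotone_in_model_loglik(self):
        l0 = -120.0
        vals = [nagelkerke_r2(l0, l1, 150) for l1 in (-120.0, -100.0, -80.0, -40.0)]
        assert vals == sorted(vals)


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 300)
        y = (rng.random(300) < p).astype(int)
        _, df, _ = hosmer_lemeshow(p, y, g=10)
        assert df == 8

    def test_perfect_calibration_scores_zero(self):
        # 10 distinct risk levels, observed event counts exactly p * 20
        p_levels = np.linspace(0.05, 0.95, 10)
        probs, ys = [], []
        for p in p_levels:
            k = round(p * 20)
            probs += [p] * 20
            ys += [1] * k + [0] * (20 - k)
        p_adj = np.repeat([k / 20 for k in (np.round(p_levels * 20))], 20)
        chi2, _, pval = hosmer_lemeshow(p_adj, np.array(ys), g=10)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert pval == pytest.approx(1.0)

    def test_matches_bruteforce_decile_binning(self):
        rng = np.random.default_rng(99)
        n = 200
        p = np.sort(rng.uniform(0.02, 0.98, n))  # distinct values
        y = (rng.random(n) < p).astype(int)
        chi2, df, _ = hosmer_lemeshow(p, y, g=10)

        # independent loop: equal-size decile bins on the sorted sample
        chi2_oracle = 0.0
        for b in range(10):
            sel = slice(b * 20, (b + 1) * 20)
            e1, e0 = p[sel].sum(), (1 - p[sel]).sum()
            o1 = y[sel].sum()
            o0 = 20 - o1
            chi2_oracle += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-10)
        assert df == 8

    def test_ties_share_a_bin(self):
        p = np.array([0.3] * 30 + [0.7] * 30)
        y = np.array([0] * 30 + [1] * 30)
        chi2, df, _ = hosmer_lemeshow(p, y, g=10)
        # only two distinct fitted values -> two groups -> df = 0
        assert df == 0

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0] * 30, [0] * 30, g=3)


class TestVif:
    def test_orthogonal_predictors_give_unity(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        r = vif_screen(X)
        assert r.vif_per_predictor["a"] == pytest.approx(1.0)
        assert r.vif_per_predictor["b"] == pytest.approx(1.0)
        assert not r.flagged

    def test_duplicated_predictor_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            vif_screen(pd.DataFrame({"a": x, "b": x}))

    def test_constant_predictor_named(self):
        with pytest.raises(ValueError, match="'c'"):
            vif_screen(pd.DataFrame({"a": [1.0, 2, 3], "c": [1.0, 1, 1]}))

    def test_agrees_with_independent_lstsq(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=200)
        X = pd.DataFrame(
            {
                "x1": z + rng.normal(0, 0.8, 200),
                "x2": z + rng.normal(0, 0.8, 200),
                "x3": rng.normal(size=200),
            }
        )
        r = vif_screen(X)
        for col in X.columns:
            y = X[col].to_numpy()
            others = np.column_stack(
                [np.ones(len(X))] + [X[c].to_numpy() for c in X.columns if c != col]
            )
            beta, *_ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert r.vif_per_predictor[col] == pytest.approx(1 / (1 - r2), rel=1e-8)
            assert r.vif_per_predictor[col] >= 1.0 - 1e-12


class TestBonferroni:
    def test_published_threshold(self):
        assert f"{bonferroni_threshold(0.05, 37):.4f}" == "0.0014"

    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_exact_divisions(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 5)


class TestFitLogistic:
    def test_saturated_binary_fit_equals_closed_form(self):
        # gender x (Troubled vs Complete) counts
        a, b, c, d = 190, 244, 65, 419
        y = np.r_[np.ones(a + c), np.zeros(b + d)]
        x = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
        fit = fit_logistic(y, pd.DataFrame({"girl": x}))
        or_closed, (lo, hi) = odds_ratio_2x2(a, b, c, d)
        t = fit.terms[0]
        assert t.odds_ratio == pytest.approx(or_closed, abs=1e-6)
        assert t.ci_low == pytest.approx(lo, abs=1e-6)
        assert t.ci_high == pytest.approx(hi, abs=1e-6)

    def test_random_tables_match_cross_product(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a, b, c, d = rng.integers(3, 50, size=4)
            y = np.r_[np.ones(a + c), np.zeros(b + d)]
            x = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
            fit = fit_logistic(y, pd.DataFrame({"x": x}))
            assert fit.terms[0].odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}))

    def test_perfect_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_multivariable_recovery_at_scale(self):
        rng = np.random.default_rng(2025)
        n = 4000
        X = pd.DataFrame(
            {"girl": (rng.random(n) < 0.5).astype(float),
             "stressed": (rng.random(n) < 0.4).astype(float)}
        )
        y = simulate_logistic_outcome(X, -0.5, {"girl": 0.63, "stressed": 0.80}, rng)
        fit = fit_logistic(y, X)
        assert fit.term("girl").coef == pytest.approx(0.63, abs=0.2)
        assert fit.term("stressed").coef == pytest.approx(0.80, abs=0.2)
        assert 0 < fit.nagelkerke_r2 < 0.3
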