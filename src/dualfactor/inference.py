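"""Binary logistic-regression modelling with the full diagnostic battery.

Each status group is contrasted against the Complete-mental-health
reference group in a separate binary logistic regression (single-predictor
"unadjusted" fits, and one multivariable "adjusted" fit where group sizes
permit).  Reported per term: the coefficient, Wald standard error, odds
ratio exp(beta) with Wald/Woolf 95% CI, and p-value.  Model-level
diagnostics: Nagelkerke's rescaled Cox–Snell pseudo-R^2, the
Hosmer–Lemeshow calibration chi-squared over deciles of fitted risk, and a
variance-inflation-factor screen for multicollinearity.  Multiple testing
across the analysis is handled by a Bonferroni-corrected significance
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "odds_ratio_2x2",
    "fit_logistic",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "vif_screen",
    "bonferroni_threshold",
    "LogisticFit",
    "LogisticTerm",
    "CollinearityScreen",
    "SeparationError",
    "ZeroCellError",
]

Z_95 = stats.norm.ppf(0.975)  # 1.959963984540054


class SeparationError(RuntimeError):
    """Perfect (or quasi-) separation: the MLE does not exist."""


class ZeroCellError(ValueError):
    """A zero cell makes the closed-form odds ratio undefined."""


@dataclass(frozen=True)
class LogisticTerm:
    predictor: str
    level: str | None
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFit:
    outcome: str
    terms: list  # of LogisticTerm (intercept excluded)
    intercept: float
    n_used: int
    loglik_null: float
    loglik_model: float
    nagelkerke_r2: float
    hosmer_lemeshow: tuple | None = None  # (chi2, df, p)
    converged: bool = True

    def term(self, predictor: str) -> LogisticTerm:
        for t in self.terms:
            if t.predictor == predictor:
                return t
        raise KeyError(predictor)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": t.predictor,
                "level": t.level,
                "coef": t.coef,
                "se": t.se,
                "OR": t.odds_ratio,
                "CI95_low": t.ci_low,
                "CI95_high": t.ci_high,
                "p": t.p_value,
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


@dataclass
class CollinearityScreen:
    vif_per_predictor: dict
    max_vif: float
    flagged: bool  # max VIF >= 10


def odds_ratio_2x2(
    exposed_case: int,
    exposed_control: int,
    unexposed_case: int,
    unexposed_control: int,
    *,
    haldane: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Closed-form odds ratio with the Woolf 95% confidence interval.

    OR = (a*d)/(b*c) for a = exposed cases, b = exposed controls,
    c = unexposed cases, d = unexposed controls;
    CI95 = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

    A zero cell raises :class:`ZeroCellError` unless ``haldane=True``, in
    which case the Haldane–Anscombe +0.5 correction is applied to every
    cell.
    """
    cells = [exposed_case, exposed_control, unexposed_case, unexposed_control]
    if any(v < 0 for v in cells):
        raise ValueError("counts must be non-negative")
    if any(v == 0 for v in cells):
        if not haldane:
            raise ZeroCellError(
                "zero cell: closed-form OR undefined (pass haldane=True "
                "for the +0.5 correction)"
            )
        cells = [v + 0.5 for v in cells]
    a, b, c, d = cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), (math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se))


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Nagelkerke's rescaled Cox–Snell pseudo-R^2.

    R^2_CS = 1 - exp(2 (L0 - L1) / n), rescaled by its maximum
    1 - exp(2 L0 / n) so a saturated (perfectly predicting) model scores 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null: fit worse than null")
    l1 = max(loglik_model, loglik_null)
    r2_cs = 1.0 - math.exp(2.0 * (loglik_null - l1) / n)
    denom = 1.0 - math.exp(2.0 * loglik_null / n)
    if denom == 0:
        return 0.0
    return min(r2_cs / denom, 1.0)


def hosmer_lemeshow(fitted_probs, observed, g: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit test over ``g`` groups of fitted risk.

    Respondents are sorted by fitted probability and split into ``g``
    near-equal groups by quantiles of the fitted values; ties never split
    across groups.  chi2 = sum over groups and both outcome classes of
    (O - E)^2 / E, with df = g - 2.
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape:
        raise ValueError("fitted_probs and observed must have equal length")
    n = len(p)
    if g < 3:
        raise ValueError("need at least 3 groups")
    if n < 2 * g:
        raise ValueError(f"need n >= {2 * g} for g={g} groups")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")

    # quantile bin edges on the fitted values; identical values share a bin
    qs = np.quantile(p, np.linspace(0, 1, g + 1)[1:-1])
    bins = np.searchsorted(qs, p, side="left")

    chi2 = 0.0
    n_groups = 0
    for b in np.unique(bins):
        sel = bins == b
        e1 = p[sel].sum()
        e0 = (1 - p[sel]).sum()
        o1 = y[sel].sum()
        o0 = (~y[sel].astype(bool)).sum()
        if e1 == 0 or e0 == 0:
            raise ValueError("degenerate binning: zero expected count in a group")
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        n_groups += 1
    df = n_groups - 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def vif_screen(design: pd.DataFrame, flag_threshold: float = 10.0) -> CollinearityScreen:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from an ordinary least-squares regression of predictor j on
    all the other predictors plus an intercept.  A constant predictor or a
    perfectly collinear one (R^2 -> 1) raises an error naming it.
    """
    X = pd.DataFrame(design).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    vifs = {}
    for col in X.columns:
        y = X[col].to_numpy()
        if np.ptp(y) == 0:
            raise ValueError(f"constant predictor {col!r}")
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        fit = sm.OLS(y, others).fit()
        r2 = fit.rsquared
        if r2 > 1 - 1e-10:
            raise ValueError(f"predictor {col!r} is perfectly collinear with the others")
        vifs[col] = float(1.0 / (1.0 - r2))
    max_vif = max(vifs.values())
    return CollinearityScreen(
        vif_per_predictor=vifs, max_vif=max_vif, flagged=max_vif >= flag_threshold
    )


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / m."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if m_tests < 1:
        raise ValueError("m_tests must be a positive integer")
    return alpha / m_tests


_SEP_COEF_LIMIT = 30.0  # |beta| beyond this on a standardised design => separation


def fit_logistic(
    outcome,
    design: pd.DataFrame,
    outcome_name: str = "outcome",
    *,
    hl_groups: int | None = None,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression with Wald inference.

    Parameters
    ----------
    outcome
        Binary (0/1) response, one entry per respondent.
    design
        Numeric-coded predictor frame (dummy indicators and/or continuous
        columns); an intercept is added internally.  Rows with any missing
        value in outcome or design are dropped (complete-case).
    hl_groups
        If given, also compute the Hosmer–Lemeshow test with this many
        groups of fitted risk (conventionally 10 for multivariable fits).

    Raises
    ------
    SeparationError
        When the likelihood diverges (perfect or quasi-separation).
    ValueError
        Single-class outcome, or too few rows for the parameter count.
    """
    X = pd.DataFrame(design).astype(float)
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index)
    keep = ~(y.isna() | X.isna().any(axis=1))
    X, y = X[keep], y[keep]
    n = len(y)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    if n < X.shape[1] + 2:
        raise ValueError("too few complete rows for the number of parameters")

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y.to_numpy(), Xc.to_numpy())
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
        except (np.linalg.LinAlgError, PerfectSeparationError) as e:
            raise SeparationError(str(e)) from e

    # separation shows up as diverging coefficients / exploding SEs
    scale = np.r_[1.0, X.std(ddof=0).replace(0, 1.0).to_numpy()]
    if (
        np.any(np.abs(res.params * scale) > _SEP_COEF_LIMIT)
        or not np.all(np.isfinite(res.bse))
        or np.any(np.abs(res.bse * scale) > _SEP_COEF_LIMIT)
    ):
        raise SeparationError("diverging coefficients: perfect separation suspected")

    params = res.params
    bse = res.bse
    pvals = res.pvalues
    terms = []
    for i, col in enumerate(X.columns, start=1):
        beta, se = float(params[i]), float(bse[i])
        name, _, level = str(col).partition("[")
        terms.append(
            LogisticTerm(
                predictor=str(col),
                level=level.rstrip("]") or None,
                coef=beta,
                se=se,
                odds_ratio=math.exp(beta),
                ci_low=math.exp(beta - Z_95 * se),
                ci_high=math.exp(beta + Z_95 * se),
                p_value=float(pvals[i]),
            )
        )

    ll_model = float(res.llf)
    ll_null = float(res.llnull)
    fit = LogisticFit(
        outcome=outcome_name,
        terms=terms,
        intercept=float(params[0]),
        n_used=n,
        loglik_null=ll_null,
        loglik_model=ll_model,
        nagelkerke_r2=nagelkerke_r2(ll_null, ll_model, n),
        converged=bool(res.mle_retvals.get("converged", True)),
    )
    if hl_groups is not None:
        fit.hosmer_lemeshow = hosmer_lemeshow(res.predict(), y.to_numpy(), g=hl_groups)
    return fit
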