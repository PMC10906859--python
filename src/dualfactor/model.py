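"""Pipeline orchestration: the model / results surface.

:class:`DualFactorModel` wraps a respondent-level survey table and
``fit()`` runs the full analysis — exclusion cascade, instrument scoring,
four-group classification, group comparisons, and logistic regressions —
returning a :class:`DualFactorResults` object that carries the estimates,
their uncertainties and diagnostics, renders the report tables
(descriptives, instrument summary, status cross-table, group comparisons,
unadjusted odds ratios, and the adjusted multivariable model), and writes
them to disk together with a reproducibility manifest.

Typical use::

    from dualfactor import DualFactorModel, SimConfig, generate_cohort

    cohort = generate_cohort(SimConfig(n_respondents=2208, seed=1))
    results = DualFactorModel(cohort).fit()
    print(results.summary())
    results.save("results/")
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import (
    CYRM_COLUMNS,
    DEFAULT_REQUIRED_VARIABLES,
    MHC_COLUMNS,
    SDQ_COLUMNS,
    apply_exclusions,
    derive_covariates,
    read_cohort_csv,
)
from .dual_factor import STATUS_ABBREV, STATUSES, classify, round_half_up, tabulate
from .group_stats import compare_categorical, compare_continuous, spearman_rho
from .inference import (
    ZeroCellError,
    bonferroni_threshold,
    fit_logistic,
    vif_screen,
)
from .instruments import cronbach_alpha, score_mhcsf, score_sdq
from scipy import stats as _scistats

logger = logging.getLogger(__name__)

# binary analysis variables: (name, level counted as "exposed")
CATEGORICAL_PREDICTORS = [
    ("gender", "girl"),
    ("birth_country", "other"),
    ("guardian_unemployed_or_sickleave", "at_least_one"),
    ("school_level", "upper"),
    ("grade_f", "at_least_one"),
    ("truancy", "ever"),
    ("stressed", "considerable"),
]
CONTINUOUS_PREDICTORS = ["resilience_score", "sss"]


@dataclass
class AnalysisConfig:
    """Tunable analysis settings (defaults mirror the standard protocol)."""

    sdq_caseness_cutoff: int = 20
    mhc_strict: bool = False  # complete-case MHC categorisation
    apply_exclusions: bool = True
    required_variables: list = field(default_factory=lambda: list(DEFAULT_REQUIRED_VARIABLES))
    fisher_expected_threshold: float = 5.0
    alpha: float = 0.05
    m_tests: int | None = None  # None: count the tests actually run
    multivariable: bool = True
    hl_groups: int = 10

    @classmethod
    def from_mapping(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


def score_cohort(records: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Score instruments and classify every respondent.

    Returns ``records`` augmented with derived covariates, instrument
    scores (``mhc_total``, ``mhc_category``, ``mhc_collapsed``,
    ``sdq_total``, ``sdq_caseness`` and the four problem subscales,
    ``resilience_score``) and the dual-factor ``status`` (missing where
    either input band is missing).
    """
    config = config or AnalysisConfig()
    out = records.copy()
    cov = derive_covariates(records)
    for c in cov.columns:
        out[c] = cov[c]

    mhc_items = records[MHC_COLUMNS].to_numpy(dtype=float)
    sdq_items = records[SDQ_COLUMNS].to_numpy(dtype=float)

    mhc_rows = [score_mhcsf(row, strict=config.mhc_strict) for row in mhc_items]
    sdq_rows = [score_sdq(row) for row in sdq_items]

    out["mhc_total"] = [s.total for s in mhc_rows]
    out["mhc_category"] = [s.category for s in mhc_rows]
    out["mhc_collapsed"] = [s.collapsed for s in mhc_rows]
    # subscale totals (emotional 1-3, social 4-8, psychological 9-14) are
    # emitted for completeness but not analysed downstream
    for name, sl in [("emotional", slice(0, 3)), ("social", slice(3, 8)),
                     ("psychological", slice(8, 14))]:
        block = mhc_items[:, sl]
        totals = block.sum(axis=1)
        totals[np.isnan(block).any(axis=1)] = np.nan
        out[f"mhc_{name}_total"] = totals
    out["sdq_total"] = [s.total_difficulties for s in sdq_rows]
    for sub in ("emotional", "conduct", "hyperactivity", "peer", "prosocial"):
        out[f"sdq_{sub}"] = [getattr(s, sub) for s in sdq_rows]
    out["sdq_caseness"] = [
        None if s.total_difficulties is None
        else s.total_difficulties >= config.sdq_caseness_cutoff
        for s in sdq_rows
    ]
    out["status"] = [
        classify(m, c) for m, c in zip(out["mhc_collapsed"], out["sdq_caseness"])
    ]
    return out


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


class DualFactorModel:
    """Dual-factor mental-health analysis of a respondent-level survey table.

    Parameters
    ----------
    data
        Cohort DataFrame in the canonical column layout (see
        :mod:`dualfactor.cohort`); use :meth:`from_csv` with a codebook to
        ingest externally named tables.
    config
        :class:`AnalysisConfig` or a plain mapping of its fields.
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig | dict | None = None):
        if isinstance(config, dict):
            config = AnalysisConfig.from_mapping(config)
        self.data = data.reset_index(drop=True)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, codebook=None, config=None) -> "DualFactorModel":
        return cls(read_cohort_csv(path, codebook), config)

    def fit(self) -> "DualFactorResults":
        cfg = self.config
        warnings_log: list[str] = []

        if cfg.apply_exclusions:
            retained, audit = apply_exclusions(self.data, cfg.required_variables)
        else:
            from .cohort import ExclusionAudit

            retained = self.data
            audit = ExclusionAudit(len(self.data), 0, 0, 0, len(self.data))

        scored = score_cohort(retained, cfg).reset_index(drop=True)
        dist = tabulate(scored["status"])
        n_unclassified = int(scored["status"].isna().sum())
        if n_unclassified:
            warnings_log.append(f"{n_unclassified} respondents unclassified")

        n_tests = 0
        comparisons = []
        status = scored["status"]
        for var, level in CATEGORICAL_PREDICTORS:
            flags_by_group = {}
            for s in STATUSES:
                vals = scored.loc[status == s, var]
                vals = vals[vals.notna()]
                if len(vals):
                    flags_by_group[STATUS_ABBREV[s]] = (vals == level).to_numpy()
            if len(flags_by_group) < 2:
                warnings_log.append(f"comparison skipped for {var}: <2 groups")
                continue
            comparisons.append(
                compare_categorical(
                    flags_by_group, variable=f"{var}={level}",
                    fisher_expected_threshold=cfg.fisher_expected_threshold,
                )
            )
            n_tests += 1
        for var in CONTINUOUS_PREDICTORS:
            sel = status.notna() & scored[var].notna()
            try:
                comparisons.append(
                    compare_continuous(
                        scored.loc[sel, var].to_numpy(dtype=float),
                        status[sel].map(STATUS_ABBREV).to_numpy(),
                        variable=var,
                    )
                )
                n_tests += 1
            except ValueError as e:
                warnings_log.append(f"comparison skipped for {var}: {e}")

        # unadjusted single-predictor logistic fits, each group vs Complete
        univariate: dict[str, dict] = {}
        design_all = self._design_matrix(scored)
        for s in ("symptomatic_but_content", "vulnerable", "troubled"):
            abbrev = STATUS_ABBREV[s]
            sel = status.isin([s, "complete"])
            y = (status[sel] == s).astype(int)
            fits = {}
            for col in design_all.columns:
                try:
                    fits[col] = fit_logistic(
                        y, design_all.loc[sel, [col]],
                        outcome_name=f"{abbrev} vs C",
                    )
                    n_tests += 1
                except (ValueError, RuntimeError) as e:
                    warnings_log.append(f"univariate fit {abbrev} vs C / {col}: {e}")
            univariate[abbrev] = fits

        # adjusted multivariable model, Vulnerable vs Complete, complete-case
        multivariable = None
        vif = None
        if cfg.multivariable:
            sel = status.isin(["vulnerable", "complete"])
            y = (status[sel] == "vulnerable").astype(int)
            X = design_all.loc[sel]
            try:
                multivariable = fit_logistic(
                    y, X, outcome_name="V vs C (adjusted)", hl_groups=cfg.hl_groups
                )
                n_tests += 1
                complete = X.dropna()
                vif = vif_screen(complete)
            except (ValueError, RuntimeError) as e:
                warnings_log.append(f"multivariable fit: {e}")

        m = cfg.m_tests if cfg.m_tests is not None else max(n_tests, 1)
        threshold = bonferroni_threshold(cfg.alpha, m)
        for c in comparisons:
            c.significant = c.p_value < threshold

        manifest = {
            "package_version": _pkg_version,
            "input_sha256": hashlib.sha256(
                pd.util.hash_pandas_object(self.data.astype(str)).to_numpy().tobytes()
            ).hexdigest(),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(cfg).items()},
            "n_input": audit.n_input,
            "n_retained": audit.n_final,
            "n_classified": dist.n_classified,
            "n_unclassified": n_unclassified,
            "n_tests_performed": n_tests,
            "bonferroni_m": m,
            "bonferroni_threshold": threshold,
            "warnings": warnings_log,
        }
        return DualFactorResults(
            scored=scored,
            exclusion_audit=audit,
            status_distribution=dist,
            comparisons=comparisons,
            univariate=univariate,
            multivariable=multivariable,
            vif=vif,
            alpha_threshold=threshold,
            manifest=manifest,
            config=cfg,
        )

    @staticmethod
    def _design_matrix(scored: pd.DataFrame) -> pd.DataFrame:
        """Numeric design: reference-coded dummies + untransformed continuous."""
        X = pd.DataFrame(index=scored.index)
        for var, level in CATEGORICAL_PREDICTORS:
            col = scored[var]
            X[f"{var}[{level}]"] = np.where(col.isna(), np.nan, (col == level).astype(float))
        for var in CONTINUOUS_PREDICTORS:
            X[var] = scored[var].astype(float)
        return X


@dataclass
class DualFactorResults:
    """Fitted analysis: estimates, diagnostics and report tables."""

    scored: pd.DataFrame
    exclusion_audit: object
    status_distribution: object
    comparisons: list
    univariate: dict
    multivariable: object | None
    vif: object | None
    alpha_threshold: float
    manifest: dict
    config: AnalysisConfig

    # ------------------------------------------------------------------ tables
    def table_descriptives(self) -> pd.DataFrame:
        """Cohort descriptives: n (%) per analysis-covariate level."""
        rows = []
        n = len(self.scored)
        for var, _ in CATEGORICAL_PREDICTORS:
            counts = self.scored[var].value_counts(dropna=True)
            for cat, c in counts.items():
                rows.append({
                    "variable": var, "category": cat, "n": int(c),
                    "percent": round_half_up(100.0 * c / counts.sum(), 1),
                })
        for var in CONTINUOUS_PREDICTORS:
            vals = self.scored[var].dropna().astype(float)
            rows.append({
                "variable": var, "category": "mean (SD)", "n": len(vals),
                "percent": None,
                "mean": round(vals.mean(), 1), "sd": round(vals.std(ddof=1), 1),
            })
        df = pd.DataFrame(rows)
        df.attrs["n_total"] = n
        return df

    def table_instruments(self) -> pd.DataFrame:
        """Instrument summary: totals (mean, SD, median, P10, P90) + bands."""
        rows = []
        for name, total_col, band_col, band_levels in [
            ("MHC-SF", "mhc_total", "mhc_collapsed", ["flourishing", "moderate_to_low"]),
            ("SDQ", "sdq_total", "sdq_caseness", [True, False]),
        ]:
            vals = self.scored[total_col].dropna().astype(float)
            rows.append({
                "instrument": name, "level": "total score",
                "n": len(vals), "percent": None,
                "mean": round(vals.mean(), 2), "sd": round(vals.std(ddof=1), 1),
                "median": float(np.percentile(vals, 50)),
                "p10": float(np.percentile(vals, 10)),
                "p90": round(float(np.percentile(vals, 90)), 1),
            })
            band = self.scored[band_col].dropna()
            for lev in band_levels:
                c = int((band == lev).sum())
                rows.append({
                    "instrument": name, "level": str(lev), "n": c,
                    "percent": round_half_up(100.0 * c / len(band), 1),
                })
        return pd.DataFrame(rows)

    def table_status(self) -> pd.DataFrame:
        """Four-group distribution (2x2 cross) with an independence test.

        The p-value is a Pearson chi-squared test of independence of the
        two bands on the 2x2 table — our interpretation of the customary
        cross-table test; the test for this table is not standardised.
        """
        d = self.status_distribution
        t = np.array([
            [d.counts["complete"], d.counts["symptomatic_but_content"]],
            [d.counts["vulnerable"], d.counts["troubled"]],
        ])
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            _, p, _, _ = _scistats.chi2_contingency(t, correction=False)
        else:
            p = np.nan
        rows = [
            {"status": s, "abbrev": STATUS_ABBREV[s], "n": d.counts[s],
             "percent": d.proportions[s]}
            for s in STATUSES
        ]
        df = pd.DataFrame(rows)
        df.attrs["independence_p"] = float(p)
        return df

    def table_group_comparisons(self) -> pd.DataFrame:
        """Per-variable omnibus test + pairwise effect sizes (magnitudes)."""
        rows = []
        for c in self.comparisons:
            pair_fmt = "; ".join(
                f"{a} vs {b} = {es:.2f}" for (a, b), es, _ in c.pairwise
            )
            rows.append({
                "variable": c.variable, "test": c.test,
                "statistic": None if np.isnan(c.statistic) else round(c.statistic, 2),
                "df": str(c.df), "p": _fmt_p(c.p_value),
                "significant": c.significant,
                "pairwise_effect_sizes": pair_fmt,
            })
        return pd.DataFrame(rows)

    def table_univariate(self) -> pd.DataFrame:
        """Unadjusted ORs (95% CI), p and Nagelkerke R2, per outcome group."""
        rows = []
        for abbrev, fits in self.univariate.items():
            for col, fit in fits.items():
                t = fit.terms[0]
                rows.append({
                    "outcome": f"{abbrev} vs C", "predictor": col,
                    "OR": round(t.odds_ratio, 2),
                    "CI95": f"{t.ci_low:.2f}-{t.ci_high:.2f}",
                    "p": _fmt_p(t.p_value),
                    "nagelkerke_r2": round(fit.nagelkerke_r2, 2),
                    "n": fit.n_used,
                })
        return pd.DataFrame(rows)

    def table_multivariable(self) -> pd.DataFrame | None:
        """Adjusted model (V vs C): ORs, CI, p, R2, Hosmer–Lemeshow."""
        if self.multivariable is None:
            return None
        fit = self.multivariable
        rows = [
            {
                "predictor": t.predictor, "OR": round(t.odds_ratio, 2),
                "CI95": f"{t.ci_low:.2f}-{t.ci_high:.2f}", "p": _fmt_p(t.p_value),
            }
            for t in fit.terms
        ]
        df = pd.DataFrame(rows)
        df.attrs["nagelkerke_r2"] = round(fit.nagelkerke_r2, 2)
        if fit.hosmer_lemeshow:
            chi2, dof, p = fit.hosmer_lemeshow
            df.attrs["hosmer_lemeshow"] = f"{chi2:.2f} ({dof}) p={p:.3f}"
        df.attrs["n"] = fit.n_used
        return df

    def tables(self) -> dict:
        out = {
            "descriptives": self.table_descriptives(),
            "instruments": self.table_instruments(),
            "status": self.table_status(),
            "group_comparisons": self.table_group_comparisons(),
            "univariate_or": self.table_univariate(),
        }
        mv = self.table_multivariable()
        if mv is not None:
            out["multivariable_or"] = mv
        return out

    # ------------------------------------------------------------- diagnostics
    def wellbeing_problems_correlation(self) -> float:
        """Spearman correlation of MHC total vs SDQ total (complete pairs)."""
        sel = self.scored["mhc_total"].notna() & self.scored["sdq_total"].notna()
        return spearman_rho(
            self.scored.loc[sel, "mhc_total"].astype(float),
            self.scored.loc[sel, "sdq_total"].astype(float),
        )

    def reliability(self) -> dict:
        """Cronbach's alpha for MHC-SF, SDQ total difficulties and CYRM-12."""
        sdq_scored = self.scored[SDQ_COLUMNS].to_numpy(dtype=float).copy()
        from .instruments import SDQ_REVERSE_ITEMS, SDQ_SUBSCALES

        difficulty = sorted(
            i for k, v in SDQ_SUBSCALES.items() if k != "prosocial" for i in v
        )
        for i in SDQ_REVERSE_ITEMS:
            sdq_scored[:, i - 1] = 2 - sdq_scored[:, i - 1]
        return {
            "mhc": cronbach_alpha(self.scored[MHC_COLUMNS].to_numpy(dtype=float)).alpha,
            "sdq": cronbach_alpha(sdq_scored[:, [i - 1 for i in difficulty]]).alpha,
            "cyrm": cronbach_alpha(self.scored[CYRM_COLUMNS].to_numpy(dtype=float)).alpha,
        }

    # ------------------------------------------------------------------ output
    def summary(self) -> str:
        a = self.exclusion_audit
        d = self.status_distribution
        lines = [
            "Dual-factor mental-health analysis",
            "==================================",
            f"input records            {a.n_input}",
            f"  height/weight outliers {a.n_heightweight_outliers}",
            f"  other/unsure gender    {a.n_gender_other_or_unsure}",
            f"  missing required       {a.n_missing_required}",
            f"retained                 {a.n_final}",
            "",
            "Status groups (of classified respondents):",
        ]
        for s in STATUSES:
            lines.append(
                f"  {STATUS_ABBREV[s]} {s:<24s} n = {d.counts[s]:>5d}  ({d.proportions[s]}%)"
            )
        lines.append("")
        try:
            rho = self.wellbeing_problems_correlation()
            lines.append(f"MHC-SF vs SDQ Spearman rho: {rho:.2f}")
        except ValueError:
            pass
        lines.append(
            f"Bonferroni threshold: {self.alpha_threshold:.4f} "
            f"(alpha={self.config.alpha}, m={self.manifest['bonferroni_m']})"
        )
        if self.multivariable is not None:
            fit = self.multivariable
            lines.append(
                f"Adjusted model (V vs C): n={fit.n_used}, "
                f"Nagelkerke R2={fit.nagelkerke_r2:.2f}"
            )
            if fit.hosmer_lemeshow:
                chi2, dof, p = fit.hosmer_lemeshow
                lines.append(f"  Hosmer-Lemeshow chi2={chi2:.2f} ({dof}) p={p:.3f}")
        if self.vif is not None:
            lines.append(
                f"VIF range {min(self.vif.vif_per_predictor.values()):.2f}-"
                f"{self.vif.max_vif:.2f}"
                + (" (collinearity flagged)" if self.vif.flagged else "")
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write all tables (TSV), the manifest (JSON) and a text summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            extra = {k: v for k, v in df.attrs.items()}
            if extra:
                (out / f"{name}.attrs.json").write_text(
                    json.dumps(extra, indent=2, default=str) + "\n"
                )
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str) + "\n"
        )
        (out / "summary.txt").write_text(self.summary() + "\n")
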