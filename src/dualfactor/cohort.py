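"""Cohort table handling: codebook, covariate derivation, exclusion cascade.

The respondent-level table is a pandas DataFrame with one row per
respondent.  Canonical column names:

* ``respondent_id``
* raw categoricals: ``gender_raw``, ``grade`` (7–12), ``birth_country_raw``,
  ``guardian_a_occupation``, ``guardian_b_occupation``, ``grade_f_raw``,
  ``truancy_raw``, ``stress_raw``
* items: ``mhc_01``..``mhc_14`` (0–5), ``sdq_01``..``sdq_25`` (0–2),
  ``cyrm_01``..``cyrm_12`` (1–5)
* ``sss`` (1–10), ``height`` (cm), ``weight`` (kg)

A JSON codebook maps arbitrary input column names and category codes onto
this canonical layout, so externally collected tables can be ingested
without renaming by hand.

Analysis covariates are dichotomised from the raw questions exactly as the
survey's analysis plan prescribes (e.g. "stressed to a considerable
extent" iff the raw answer is "fairly much" or "very much"); see
:func:`derive_covariates`.

The exclusion cascade drops, in order: (1) respondents whose height or
weight lies beyond two standard deviations from the input-set mean
(a routine screen against unreliable responding), (2) respondents with
other/unsure gender identity, (3) respondents missing any required
analysis variable (listwise).  Each excluded respondent is recorded once,
under the first rule that fired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MHC_COLUMNS",
    "SDQ_COLUMNS",
    "CYRM_COLUMNS",
    "DEFAULT_REQUIRED_VARIABLES",
    "CATEGORY_CODES",
    "default_codebook",
    "write_codebook",
    "read_cohort_csv",
    "write_cohort_csv",
    "derive_covariates",
    "apply_exclusions",
    "ExclusionAudit",
]

MHC_COLUMNS = [f"mhc_{i:02d}" for i in range(1, 15)]
SDQ_COLUMNS = [f"sdq_{i:02d}" for i in range(1, 26)]
CYRM_COLUMNS = [f"cyrm_{i:02d}" for i in range(1, 13)]

RAW_CATEGORICALS = [
    "gender_raw",
    "birth_country_raw",
    "guardian_a_occupation",
    "guardian_b_occupation",
    "grade_f_raw",
    "truancy_raw",
    "stress_raw",
]

ALL_COLUMNS = (
    ["respondent_id", "gender_raw", "grade", "birth_country_raw",
     "guardian_a_occupation", "guardian_b_occupation", "grade_f_raw",
     "truancy_raw", "stress_raw"]
    + MHC_COLUMNS + SDQ_COLUMNS + CYRM_COLUMNS
    + ["sss", "height", "weight"]
)

CATEGORY_CODES = {
    "gender_raw": ["girl", "boy", "other", "unsure"],
    "birth_country_raw": ["sweden", "europe_other", "world_other"],
    "guardian_a_occupation": [
        "working", "studying", "unemployed", "longterm_sickleave",
        "sickleave_short", "other_occupation", "unknown",
    ],
    "guardian_b_occupation": [
        "working", "studying", "unemployed", "longterm_sickleave",
        "sickleave_short", "other_occupation", "unknown",
        "no_second_guardian",
    ],
    "grade_f_raw": ["none", "one_two", "three_four", "five_plus"],
    "truancy_raw": [
        "no", "per_semester", "per_month", "two_three_month",
        "per_week", "several_week",
    ],
    "stress_raw": ["no", "some_extent", "fairly_much", "very_much"],
}

# Occupation answers counting toward the "unemployed or on long-term
# sick-leave / retired due to disability" guardian flag.
GUARDIAN_FLAG_CODES = {"unemployed", "longterm_sickleave"}

# Variables whose missingness triggers listwise exclusion by default:
# gender, country of birth, guardian occupations, grade, grade-F question,
# truancy, stress, the resilience items and the SDQ items.  MHC-SF items
# and the SSS ladder are deliberately NOT required (incomplete responders
# on those were retained in the analysis).
DEFAULT_REQUIRED_VARIABLES = (
    ["gender_raw", "birth_country_raw", "guardian_a_occupation",
     "guardian_b_occupation", "grade", "grade_f_raw", "truancy_raw",
     "stress_raw"]
    + CYRM_COLUMNS + SDQ_COLUMNS
)


class CodebookError(ValueError):
    pass


def default_codebook() -> dict:
    """Identity codebook for the canonical column layout."""
    return {
        "columns": {c: c for c in ALL_COLUMNS},
        "categories": {var: {c: c for c in codes} for var, codes in CATEGORY_CODES.items()},
    }


def write_codebook(path, codebook: dict | None = None) -> None:
    cb = codebook if codebook is not None else default_codebook()
    Path(path).write_text(json.dumps(cb, indent=2) + "\n")


def read_cohort_csv(path, codebook: dict | str | Path | None = None) -> pd.DataFrame:
    """Read a respondent-level CSV and map it onto the canonical layout.

    ``codebook`` may be a dict, a path to a codebook JSON, or ``None`` for
    the identity codebook.  Unknown category codes raise
    :class:`CodebookError` naming the column and value.
    """
    if codebook is None:
        cb = default_codebook()
    elif isinstance(codebook, (str, Path)):
        cb = json.loads(Path(codebook).read_text())
    else:
        cb = codebook
    df = pd.read_csv(path, dtype={"respondent_id": str})
    rename = {src: canon for canon, src in cb["columns"].items() if src in df.columns}
    df = df.rename(columns=rename)
    missing_cols = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CodebookError(f"input lacks columns {missing_cols[:5]}...")
    for var, mapping in cb.get("categories", {}).items():
        col = df[var]
        mapped = col.map(mapping)
        bad = col.notna() & mapped.isna()
        if bad.any():
            val = col[bad].iloc[0]
            raise CodebookError(f"column {var!r}: unknown category code {val!r}")
        df[var] = mapped
    return df[ALL_COLUMNS]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _check_categories(df: pd.DataFrame) -> None:
    for var, codes in CATEGORY_CODES.items():
        col = df[var]
        bad = col.notna() & ~col.isin(codes)
        if bad.any():
            raise CodebookError(
                f"column {var!r}: unknown category code {col[bad].iloc[0]!r}"
            )


def derive_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Derive the dichotomised analysis covariates from the raw questions.

    Returns a DataFrame indexed like ``records`` with columns: ``gender``
    (girl/boy; other/unsure and missing propagate as missing),
    ``birth_country`` (sweden/other), ``guardian_unemployed_or_sickleave``
    (none/at_least_one), ``school_level`` (lower for grades 7–9, upper for
    10–12), ``grade_f`` (no_subject/at_least_one), ``truancy``
    (never/ever), ``stressed`` (no_or_some/considerable),
    ``resilience_score`` (CYRM sum, 12–60, missing if any item missing)
    and ``sss``.  Missing raw values propagate to missing derived values.
    """
    _check_categories(records)
    out = pd.DataFrame(index=records.index)

    g = records["gender_raw"]
    out["gender"] = g.where(g.isin(["girl", "boy"]))

    bc = records["birth_country_raw"]
    out["birth_country"] = np.where(
        bc.isna(), None, np.where(bc == "sweden", "sweden", "other")
    )

    ga = records["guardian_a_occupation"]
    gb = records["guardian_b_occupation"]
    flag = ga.isin(GUARDIAN_FLAG_CODES) | gb.isin(GUARDIAN_FLAG_CODES)
    either_missing = ga.isna() | gb.isna()
    # a flagged occupation on one guardian decides regardless of the other
    out["guardian_unemployed_or_sickleave"] = np.where(
        flag, "at_least_one", np.where(either_missing, None, "none")
    )

    grade = records["grade"]
    bad_grade = grade.notna() & ~grade.isin([7, 8, 9, 10, 11, 12])
    if bad_grade.any():
        raise CodebookError(f"column 'grade': unknown value {grade[bad_grade].iloc[0]!r}")
    out["school_level"] = np.where(
        grade.isna(), None, np.where(grade <= 9, "lower", "upper")
    )

    gf = records["grade_f_raw"]
    out["grade_f"] = np.where(
        gf.isna(), None, np.where(gf == "none", "no_subject", "at_least_one")
    )

    tr = records["truancy_raw"]
    out["truancy"] = np.where(tr.isna(), None, np.where(tr == "no", "never", "ever"))

    st = records["stress_raw"]
    out["stressed"] = np.where(
        st.isna(), None,
        np.where(st.isin(["fairly_much", "very_much"]), "considerable", "no_or_some"),
    )

    cyrm = records[CYRM_COLUMNS].astype(float)
    res = cyrm.sum(axis=1)
    res[cyrm.isna().any(axis=1)] = np.nan
    out["resilience_score"] = res

    out["sss"] = records["sss"].astype(float)
    return out


@dataclass
class ExclusionAudit:
    """Reconciliation of the sequential exclusion cascade."""

    n_input: int
    n_heightweight_outliers: int
    n_gender_other_or_unsure: int
    n_missing_required: int
    n_final: int
    sd_convention: str = "sample (ddof=1)"
    per_record_reasons: dict = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.n_heightweight_outliers
            + self.n_gender_other_or_unsure
            + self.n_missing_required
        )
        assert self.n_final == self.n_input - total

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_heightweight_outliers": self.n_heightweight_outliers,
            "n_gender_other_or_unsure": self.n_gender_other_or_unsure,
            "n_missing_required": self.n_missing_required,
            "n_final": self.n_final,
            "sd_convention": self.sd_convention,
        }


def apply_exclusions(
    records: pd.DataFrame,
    required_variables=None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the three-step exclusion cascade; return retained rows + audit.

    Steps, in order, each applied to the survivors of the previous one:

    1. Height/weight screen: drop rows whose height OR weight lies beyond
       mean ± 2·SD, with mean and SD computed on the *full input set*
       (sample SD, ddof=1).  Rows with missing height/weight are never
       flagged by this rule.
    2. Gender: drop rows with ``gender_raw`` in {other, unsure}.
    3. Listwise: drop rows missing any required variable
       (default :data:`DEFAULT_REQUIRED_VARIABLES`).

    Each excluded row appears in ``per_record_reasons`` exactly once, under
    the first rule that fired.  Note the height/weight bounds are fixed by
    the input set: re-running the cascade on its own output recomputes them
    on the reduced set and can, in principle, flag further rows.
    """
    if len(records) == 0:
        raise ValueError("empty input: nothing to exclude")
    if required_variables is None:
        required_variables = DEFAULT_REQUIRED_VARIABLES
    unknown = [v for v in required_variables if v not in records.columns]
    if unknown:
        raise CodebookError(f"required variables not in table: {unknown}")

    reasons: dict = {}
    ids = records["respondent_id"] if "respondent_id" in records else records.index.astype(str)

    h = records["height"].astype(float)
    w = records["weight"].astype(float)
    out_mask = pd.Series(False, index=records.index)
    for col in (h, w):
        m, s = col.mean(), col.std(ddof=1)
        out_mask |= col.notna() & ((col < m - 2 * s) | (col > m + 2 * s))
    for idx in records.index[out_mask]:
        reasons[ids.loc[idx]] = "heightweight_outlier"
    step1 = records[~out_mask]

    gmask = step1["gender_raw"].isin(["other", "unsure"])
    for idx in step1.index[gmask]:
        reasons[ids.loc[idx]] = "gender_other_or_unsure"
    step2 = step1[~gmask]

    miss = step2[list(required_variables)].isna().any(axis=1)
    for idx in step2.index[miss]:
        reasons[ids.loc[idx]] = "missing_required"
    retained = step2[~miss]

    audit = ExclusionAudit(
        n_input=len(records),
        n_heightweight_outliers=int(out_mask.sum()),
        n_gender_other_or_unsure=int(gmask.sum()),
        n_missing_required=int(miss.sum()),
        n_final=len(retained),
        per_record_reasons=reasons,
    )
    audit.check()
    return retained, audit
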