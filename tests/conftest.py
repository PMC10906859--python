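import numpy as np
import pandas as pd
import pytest

from dualfactor.cohort import ALL_COLUMNS, CYRM_COLUMNS, MHC_COLUMNS, SDQ_COLUMNS


def make_records(n: int) -> pd.DataFrame:
    """Deterministic, fully answered canonical cohort of n respondents.

    Heights/weights are tightly clustered so the 2-SD screen flags nothing
    unless a test plants outliers; every required variable is present.
    """
    i = np.arange(n)
    df = pd.DataFrame(index=i, columns=ALL_COLUMNS, dtype=object)
    df["respondent_id"] = [f"R{k:05d}" for k in i]
    df["gender_raw"] = np.where(i % 2 == 0, "girl", "boy")
    df["grade"] = 7 + (i % 6)
    df["birth_country_raw"] = "sweden"
    df["guardian_a_occupation"] = "working"
    df["guardian_b_occupation"] = "working"
    df["grade_f_raw"] = "none"
    df["truancy_raw"] = "no"
    df["stress_raw"] = "some_extent"
    for c in MHC_COLUMNS:
        df[c] = 3
    for c in SDQ_COLUMNS:
        df[c] = 1
    for c in CYRM_COLUMNS:
        df[c] = 4
    df["sss"] = 6
    # small deterministic jitter, well inside 2 SD of the cluster
    df["height"] = 170.0 + ((i * 7) % 11 - 5) / 5.0
    df["weight"] = 60.0 + ((i * 5) % 11 - 5) / 5.0
    for c in MHC_COLUMNS + SDQ_COLUMNS + CYRM_COLUMNS + ["sss", "height", "weight"]:
        df[c] = pd.to_numeric(df[c])
    df["grade"] = df["grade"].astype(int)
    return df


@pytest.fixture
def records100() -> pd.DataFrame:
    return make_records(100)
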