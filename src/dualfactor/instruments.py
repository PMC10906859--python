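"""Scoring of the survey instruments.

Three self-report instruments are scored here:

* **MHC-SF** (Mental Health Continuum — Short Form): 14 items rated 0
  ("never") to 5 ("every day") over the past month.  Items 1–3 assess
  emotional well-being; items 4–14 assess positive (social + psychological)
  functioning.  Besides the 0–70 total, the instrument defines a categorical
  diagnosis: *flourishing* requires frequent positive experiences ("almost
  every day" or "every day", i.e. a rating of 4 or 5) on at least one
  emotional item and at least six of the eleven functioning items;
  *languishing* requires infrequent experiences ("never" or "once or
  twice", a rating of 0 or 1) with the same counting rule; everything else
  is *moderate*.  For dual-factor classification, moderate and languishing
  are collapsed into a single "moderate-to-low" band.

* **SDQ** (Strengths and Difficulties Questionnaire, self-report): 25
  items rated 0–2 across five subscales (emotional symptoms, conduct
  problems, hyperactivity, peer problems, prosocial behaviour).  The total
  difficulties score (0–40) sums the four problem subscales — prosocial is
  excluded — after reverse-scoring the five positively-worded difficulty
  items.  Caseness ("possible mental health problems") is a total of 20 or
  above, the 90th percentile of a UK norm sample.

* **CYRM-12** (Child and Youth Resilience Measure): 12 items rated 1–5,
  summed to a 12–60 resilience score.

Missing-data policy is explicit in every scorer; see the individual
docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MhcScore",
    "SdqScore",
    "ReliabilityResult",
    "score_mhcsf",
    "score_sdq",
    "score_cyrm",
    "cronbach_alpha",
]

MHC_N_ITEMS = 14
MHC_EMOTIONAL = slice(0, 3)  # items 1-3
MHC_FUNCTIONING = slice(3, 14)  # items 4-14

SDQ_N_ITEMS = 25
# Standard published self-report scoring sheet (1-based item numbers).
SDQ_SUBSCALES = {
    "emotional": (3, 8, 13, 16, 24),
    "conduct": (5, 7, 12, 18, 22),
    "hyperactivity": (2, 10, 15, 21, 25),
    "peer": (6, 11, 14, 19, 23),
    "prosocial": (1, 4, 9, 17, 20),
}
# The five positively-worded difficulty items, inverted (2 - raw) before summing.
SDQ_REVERSE_ITEMS = (7, 11, 14, 21, 25)

SDQ_CASENESS_CUTOFF = 20

CYRM_N_ITEMS = 12


class ItemRangeError(ValueError):
    """An item response lies outside the instrument's declared range."""


@dataclass(frozen=True)
class MhcScore:
    """Scored MHC-SF response.

    ``total`` is present only when all 14 items were answered.  The band
    counts are computed over answered items only; unanswered items qualify
    for neither the high nor the low frequency band, so incomplete
    responders drift toward the ``moderate`` category (and hence the
    collapsed ``moderate_to_low`` band).  Use ``strict=True`` in
    :func:`score_mhcsf` for a complete-case-only categorisation.
    """

    total: int | None
    emotional_high_count: int
    functioning_high_count: int
    emotional_low_count: int
    functioning_low_count: int
    category: str | None  # flourishing | moderate | languishing
    collapsed: str | None  # flourishing | moderate_to_low
    n_answered: int


@dataclass(frozen=True)
class SdqScore:
    emotional: int | None
    conduct: int | None
    hyperactivity: int | None
    peer: int | None
    prosocial: int | None
    total_difficulties: int | None
    caseness: bool | None


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha for an item matrix (complete cases only)."""

    alpha: float
    k_items: int
    n_complete: int


def _validate_items(items, n_expected: int, lo: int, hi: int, name: str) -> list:
    if len(items) != n_expected:
        raise ValueError(f"{name} expects {n_expected} items, got {len(items)}")
    out = []
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(None)
            continue
        iv = int(v)
        if iv != v or not (lo <= iv <= hi):
            raise ItemRangeError(
                f"{name} item {i + 1}: response {v!r} outside {lo}..{hi}"
            )
        out.append(iv)
    return out


def score_mhcsf(items, *, strict: bool = False) -> MhcScore:
    """Score one MHC-SF response vector.

    Parameters
    ----------
    items
        14 responses, each in ``{0..5}`` or missing (``None``/NaN).
        Items 1–3 are the emotional well-being items, items 4–14 the
        positive-functioning items.
    strict
        If true, any missing item makes the categorical diagnosis missing
        (complete-case mode).  The default tolerates missing items: band
        counts run over answered items only, so a respondent can still
        reach flourishing or languishing if enough answered items qualify.

    Returns
    -------
    MhcScore
        ``total`` is ``None`` unless all 14 items were answered.
    """
    vals = _validate_items(items, MHC_N_ITEMS, 0, 5, "MHC-SF")
    answered = [v for v in vals if v is not None]
    n_answered = len(answered)

    emo = [v for v in vals[MHC_EMOTIONAL] if v is not None]
    fun = [v for v in vals[MHC_FUNCTIONING] if v is not None]
    emotional_high = sum(v >= 4 for v in emo)
    functioning_high = sum(v >= 4 for v in fun)
    emotional_low = sum(v <= 1 for v in emo)
    functioning_low = sum(v <= 1 for v in fun)

    total = sum(answered) if n_answered == MHC_N_ITEMS else None

    if strict and n_answered < MHC_N_ITEMS:
        category = collapsed = None
    else:
        if emotional_high >= 1 and functioning_high >= 6:
            category = "flourishing"
        elif emotional_low >= 1 and functioning_low >= 6:
            category = "languishing"
        else:
            category = "moderate"
        collapsed = "flourishing" if category == "flourishing" else "moderate_to_low"

    return MhcScore(
        total=total,
        emotional_high_count=emotional_high,
        functioning_high_count=functioning_high,
        emotional_low_count=emotional_low,
        functioning_low_count=functioning_low,
        category=category,
        collapsed=collapsed,
        n_answered=n_answered,
    )


def score_sdq(items, *, prorate: bool = False) -> SdqScore:
    """Score one SDQ self-report response vector.

    Parameters
    ----------
    items
        25 raw responses in ``{0, 1, 2}`` ("not true" / "somewhat true" /
        "certainly true") or missing, in the standard published item order.
    prorate
        Missing-item policy per subscale.  Default (``False``) is
        complete-case: a subscale with any missing item scores ``None``,
        and the total is ``None`` if any difficulty subscale is.  With
        ``prorate=True`` the standard scaling rule applies: when at least
        3 of a subscale's 5 items are answered, the subscale is the item
        mean times 5, rounded half-up to an integer.

    The five positively-worded difficulty items are inverted (``2 - raw``)
    before summing, so an all-zero raw vector still scores 10.
    """
    vals = _validate_items(items, SDQ_N_ITEMS, 0, 2, "SDQ")

    def scored(item_no: int) -> int | None:
        v = vals[item_no - 1]
        if v is None:
            return None
        return 2 - v if item_no in SDQ_REVERSE_ITEMS else v

    subscores: dict[str, int | None] = {}
    for name, item_nos in SDQ_SUBSCALES.items():
        svals = [scored(i) for i in item_nos]
        present = [v for v in svals if v is not None]
        if len(present) == 5:
            subscores[name] = sum(present)
        elif prorate and len(present) >= 3:
            # half-up rounding of scale mean x 5
            subscores[name] = int(math.floor(sum(present) / len(present) * 5 + 0.5))
        else:
            subscores[name] = None

    difficulty = [subscores[k] for k in ("emotional", "conduct", "hyperactivity", "peer")]
    if any(v is None for v in difficulty):
        total = caseness = None
    else:
        total = sum(difficulty)  # type: ignore[arg-type]
        caseness = total >= SDQ_CASENESS_CUTOFF

    return SdqScore(
        emotional=subscores["emotional"],
        conduct=subscores["conduct"],
        hyperactivity=subscores["hyperactivity"],
        peer=subscores["peer"],
        prosocial=subscores["prosocial"],
        total_difficulties=total,
        caseness=caseness,
    )


def score_cyrm(items) -> int | None:
    """Sum the 12 CYRM items (1–5 each); ``None`` if any item is missing."""
    vals = _validate_items(items, CYRM_N_ITEMS, 1, 5, "CYRM-12")
    if any(v is None for v in vals):
        return None
    return sum(vals)  # type: ignore[arg-type]


def cronbach_alpha(item_matrix) -> ReliabilityResult:
    """Cronbach's alpha for an n x k item matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample variances (divisor n-1) over complete-case rows.

    Raises
    ------
    ValueError
        Fewer than 2 items, fewer than 2 complete rows, or zero total
        variance (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be n x k with k >= 2")
    complete = x[~np.isnan(x).any(axis=1)]
    n, k = complete.shape
    if n < 2:
        raise ValueError(f"need >= 2 complete rows, got {n}")
    item_vars = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), k_items=k, n_complete=n)
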