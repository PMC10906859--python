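"""Four-group dual-factor mental-health classification.

The dual-factor model treats mental well-being and mental health problems
as distinct, correlated continua.  Crossing the collapsed MHC-SF well-being
band (flourishing vs moderate-to-low) with SDQ caseness (problems vs none)
yields four status groups:

========================  ==============  ===========
well-being band           no problems     problems
========================  ==============  ===========
flourishing               Complete (C)    Symptomatic but content (S)
moderate-to-low           Vulnerable (V)  Troubled (T)
========================  ==============  ===========
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["STATUSES", "classify", "tabulate", "StatusDistribution", "round_half_up"]

STATUSES = ("complete", "symptomatic_but_content", "vulnerable", "troubled")

STATUS_ABBREV = {
    "complete": "C",
    "symptomatic_but_content": "S",
    "vulnerable": "V",
    "troubled": "T",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 2.45 -> 2.5), used for report parity."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StatusDistribution:
    counts: dict  # status -> count
    proportions: dict  # status -> percentage of classified respondents (1 dp)
    n_classified: int


def classify(mhc_collapsed: str | None, sdq_caseness: bool | None) -> str | None:
    """Map one respondent's (well-being band, caseness) pair to a status.

    Returns ``None`` (unclassified) when either input is missing; callers
    tally unclassified respondents in an audit rather than dropping them
    silently.
    """
    if mhc_collapsed is None or sdq_caseness is None:
        return None
    if mhc_collapsed not in ("flourishing", "moderate_to_low"):
        raise ValueError(f"unknown well-being band {mhc_collapsed!r}")
    if mhc_collapsed == "flourishing":
        return "symptomatic_but_content" if sdq_caseness else "complete"
    return "troubled" if sdq_caseness else "vulnerable"


def tabulate(statuses) -> StatusDistribution:
    """Count the four groups and express them as percentages (1 dp, half-up).

    ``statuses`` is an iterable of status strings; ``None`` entries
    (unclassified respondents) are ignored here — they are reported by the
    pipeline audit, not in the distribution.
    """
    counts = Counter(s for s in statuses if s is not None)
    unknown = set(counts) - set(STATUSES)
    if unknown:
        raise ValueError(f"unknown statuses {sorted(unknown)}")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classified respondents to tabulate")
    full = {s: counts.get(s, 0) for s in STATUSES}
    props = {s: round_half_up(100.0 * c / n, 1) for s, c in full.items()}
    return StatusDistribution(counts=full, proportions=props, n_classified=n)
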