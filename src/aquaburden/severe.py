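"""Severe illness: surveillance counts to hospitalizations and deaths.

Passive outbreak surveillance detects only a fraction of community cases.
Observed annual cases per pathogen are scaled up by a community multiplier
(25.5 in general, from foodborne-outbreak validation studies; 1.1 for
vibriosis; 1.0 for Naegleria fowleri, which is essentially always diagnosed).
Pathogen-specific hospitalization and death fractions then yield severe
outcomes, to which a doubling correction is applied for underdiagnosis and
underreporting of hospitalizations and deaths themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "SevereOutcome",
    "adjust_for_underreporting",
    "severe_outcomes",
    "aggregate_severe",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SevereOutcome:
    """Annual severe-outcome counts for one pathogen."""

    pathogen: str
    community_cases: ArrayLike
    hospitalizations: ArrayLike
    deaths: ArrayLike


def adjust_for_underreporting(observed: ArrayLike, multiplier: ArrayLike) -> ArrayLike:
    """Estimated community cases: observed surveillance cases x multiplier."""
    if np.any(np.asarray(observed) < 0):
        raise ValueError("invalid parameter: observed cases must be >= 0")
    if np.any(np.asarray(multiplier) < 1):
        raise ValueError("invalid multiplier: must be >= 1")
    return observed * multiplier


def severe_outcomes(
    community_cases: ArrayLike,
    hosp_fraction: ArrayLike,
    death_fraction: ArrayLike,
    severe_correction: ArrayLike = 2.0,
    pathogen: str = "",
) -> SevereOutcome:
    """Hospitalizations and deaths from community cases.

    Both severe outcomes get the ``severe_correction`` doubling; fractions
    apply to community (multiplier-adjusted) cases.
    """
    for name, frac in (("hosp_fraction", hosp_fraction), ("death_fraction", death_fraction)):
        arr = np.asarray(frac)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"invalid parameter: {name} must be in [0, 1]")
    if np.any(np.asarray(severe_correction) < 1):
        raise ValueError("invalid multiplier: severe_correction must be >= 1")
    return SevereOutcome(
        pathogen=pathogen,
        community_cases=community_cases,
        hospitalizations=community_cases * hosp_fraction * severe_correction,
        deaths=community_cases * death_fraction * severe_correction,
    )


def aggregate_severe(outcomes: Iterable[SevereOutcome]):
    """Component-wise totals: (hospitalizations, deaths) over pathogens."""
    hosp: ArrayLike = 0.0
    deaths: ArrayLike = 0.0
    for o in outcomes:
        hosp = hosp + o.hospitalizations
        deaths = deaths + o.deaths
    return hosp, deaths
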