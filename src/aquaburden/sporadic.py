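"""Sporadic (non-outbreak) illness: attributable risk and severity split.

The attributable risk (AR) for an (activity, illness) pair is the risk
difference between recreators and non-recreators over the same recall window.
Annual sporadic cases are recreation events x AR; cases divide into a mild
tier (no healthcare contact) and a moderate tier (healthcare-provider or
emergency-department contact) by an illness-specific moderate fraction.

Negative AR draws (cohort confidence intervals that cross zero) propagate by
default, mirroring an untruncated main analysis; ``truncate_at_zero`` floors
the AR at zero as a sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "CaseLoad",
    "attributable_risk",
    "expected_cases",
    "split_severity",
    "moderate_share_overall",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class CaseLoad:
    """Annual sporadic cases for one (activity, illness) pair."""

    activity: str
    illness: str
    total_cases: ArrayLike
    mild_cases: ArrayLike
    moderate_cases: ArrayLike


def attributable_risk(
    p_exposed: ArrayLike, p_unexposed: ArrayLike, truncate_at_zero: bool = False
) -> ArrayLike:
    """Risk difference p_exposed - p_unexposed, optionally floored at zero."""
    ar = np.asarray(p_exposed, dtype=float) - np.asarray(p_unexposed, dtype=float)
    if truncate_at_zero:
        ar = np.maximum(ar, 0.0)
    return ar if ar.ndim else float(ar)


def expected_cases(person_days: ArrayLike, ar: ArrayLike) -> ArrayLike:
    """Annual cases: recreation events x attributable risk.

    May be negative when the AR draw is negative and truncation is off; the
    negative values propagate into the totals.
    """
    if np.any(np.asarray(person_days) < 0):
        raise ValueError("invalid parameter: person_days must be >= 0")
    return person_days * ar


def split_severity(total_cases: ArrayLike, moderate_fraction: ArrayLike):
    """Split total cases into (mild, moderate) by the moderate fraction."""
    frac = np.asarray(moderate_fraction, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("invalid parameter: moderate_fraction must be in [0, 1]")
    moderate = total_cases * frac
    mild = total_cases - moderate
    return mild, moderate


def moderate_share_overall(caseloads: Iterable[CaseLoad]) -> ArrayLike:
    """Share of all sporadic cases that are moderate, across illness types."""
    total: ArrayLike = 0.0
    moderate: ArrayLike = 0.0
    for c in caseloads:
        total = total + c.total_cases
        moderate = moderate + c.moderate_cases
    if np.all(np.asarray(total) == 0):
        raise ValueError("no cases")
    return moderate / total
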