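"""Recreation-event exposure: from participation proportions to person-days.

One "recreation event" is one person-day of one activity.  Annual events per
activity are (adult recreators + child recreators) x mean days per recreator,
with adult recreators = participation x adult census population and child
recreators = under-16 share x under-16 census population.

All operations accept scalars or equal-length numpy arrays (one entry per
Monte Carlo draw) and are degree-1 homogeneous in each population base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "ActivityExposure",
    "recreators_over16",
    "recreators_under16",
    "person_days",
    "total_events",
    "recreators_from_child_ratio",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ActivityExposure:
    """Annual exposure for one activity (per draw when fields are arrays)."""

    activity: str
    recreators_over16: ArrayLike
    recreators_under16: ArrayLike
    person_days: ArrayLike


def _require_nonnegative(name: str, value: ArrayLike) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"invalid parameter: {name} must be >= 0")


def recreators_over16(participation: ArrayLike, adult_population: ArrayLike) -> ArrayLike:
    """Number of recreators aged >= 16: participation x adult population."""
    _require_nonnegative("participation", participation)
    _require_nonnegative("adult_population", adult_population)
    return participation * adult_population


def recreators_under16(under16_share: ArrayLike, child_population: ArrayLike) -> ArrayLike:
    """Number of recreators aged < 16: share x under-16 population."""
    _require_nonnegative("under16_share", under16_share)
    _require_nonnegative("child_population", child_population)
    return under16_share * child_population


def recreators_from_child_ratio(recreators_over16: ArrayLike, child_ratio: ArrayLike) -> ArrayLike:
    """Alternative child-recreator estimate: cohort ratio of children to adults.

    Not used by the default pipeline (which takes the share of the under-16
    census population); provided for sensitivity analysis against the cohort
    composition convention.
    """
    _require_nonnegative("recreators_over16", recreators_over16)
    _require_nonnegative("child_ratio", child_ratio)
    return recreators_over16 * child_ratio


def person_days(recreators_total: ArrayLike, mean_days: ArrayLike) -> ArrayLike:
    """Annual recreation events: recreators x mean days per recreator."""
    return recreators_total * mean_days


def total_events(exposures: Iterable[ActivityExposure]) -> ArrayLike:
    """Total annual recreation events summed over activities."""
    total: ArrayLike = 0.0
    for e in exposures:
        total = total + e.person_days
    return total
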