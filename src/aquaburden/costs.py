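"""Cost aggregation per severity tier.

The cost of illness for severity tier *i* is

    Cost_i = OTC_i + Rx_i + HCP_i + ED_i + Hospital_i
             + Sequelae_i + Productivity_i + VSL_i

where the tiers compose different subsets: mild illness (no healthcare
contact) incurs only OTC, prescription, and lost-productivity costs; moderate
illness adds healthcare-provider and emergency-department visits; severe
illness (hospitalization or death) incurs all eight components, with deaths
monetized at the value of a statistical life (VSL).  All monetary inputs are
expressed in reference-year USD; :func:`inflation_adjust` converts amounts
from other years using consumer-price-index factors specific to medical
commodities, medical services, or wages.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Tier",
    "TIERS",
    "CostBreakdown",
    "inflation_adjust",
    "component_cost",
    "productivity_cost",
    "mortality_cost",
    "sequelae_cost",
    "severity_cost",
    "per_case_cost",
]

ArrayLike = Union[float, np.ndarray]

Tier = Literal["mild", "moderate", "severe"]
TIERS: tuple[Tier, ...] = ("mild", "moderate", "severe")

#: components allowed to be non-zero in each tier
_TIER_COMPONENTS: dict[str, tuple[str, ...]] = {
    "mild": ("otc", "rx", "productivity"),
    "moderate": ("otc", "rx", "hcp", "ed", "productivity"),
    "severe": ("otc", "rx", "hcp", "ed", "hospital", "death_vsl", "sequelae", "productivity"),
}

_COMPONENTS = ("otc", "rx", "hcp", "ed", "hospital", "death_vsl", "sequelae", "productivity")


@dataclass(frozen=True)
class CostBreakdown:
    """Annual USD cost components for one severity tier (per draw if arrays)."""

    tier: str
    otc: ArrayLike = 0.0
    rx: ArrayLike = 0.0
    hcp: ArrayLike = 0.0
    ed: ArrayLike = 0.0
    hospital: ArrayLike = 0.0
    death_vsl: ArrayLike = 0.0
    sequelae: ArrayLike = 0.0
    productivity: ArrayLike = 0.0

    @property
    def total(self) -> ArrayLike:
        """Sum of the eight components (the per-tier cost identity)."""
        return (self.otc + self.rx + self.hcp + self.ed + self.hospital
                + self.death_vsl + self.sequelae + self.productivity)

    def components(self) -> dict[str, ArrayLike]:
        return {name: getattr(self, name) for name in _COMPONENTS}


def inflation_adjust(
    amount: ArrayLike,
    year: int,
    series: str,
    cpi_factors: Mapping[tuple[int, str], float],
) -> ArrayLike:
    """Convert an amount from ``year`` USD to reference-year USD.

    ``cpi_factors`` maps (year, series) to the multiplicative factor into the
    reference year; the reference year itself must carry factor 1.
    """
    key = (year, series)
    if key not in cpi_factors:
        raise KeyError(f"unknown CPI key: {key}")
    return amount * cpi_factors[key]


def component_cost(n_cases: ArrayLike, usage_probability: ArrayLike, unit_cost: ArrayLike) -> ArrayLike:
    """Expected cost of one utilization component: cases x P(use) x unit cost."""
    p = np.asarray(usage_probability)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("invalid parameter: usage_probability must be in [0, 1]")
    return n_cases * usage_probability * unit_cost


def productivity_cost(
    n_cases: ArrayLike, p_work_loss: ArrayLike, lost_hours: ArrayLike, wage: ArrayLike
) -> ArrayLike:
    """Indirect cost of missed work: cases x P(work loss) x hours x wage."""
    p = np.asarray(p_work_loss)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("invalid parameter: p_work_loss must be in [0, 1]")
    for name, v in (("lost_hours", lost_hours), ("wage", wage)):
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"invalid parameter: {name} must be >= 0")
    return n_cases * p_work_loss * lost_hours * wage


def mortality_cost(deaths: ArrayLike, vsl: ArrayLike) -> ArrayLike:
    """Mortality cost: deaths x value of a statistical life."""
    if np.any(np.asarray(deaths) < 0):
        raise ValueError("invalid parameter: deaths must be >= 0")
    return deaths * vsl


def sequelae_cost(
    hospitalizations_by_pathogen: Mapping[str, ArrayLike],
    sequelae_profiles: Mapping[str, Sequence[tuple[str, ArrayLike, ArrayLike]]],
) -> ArrayLike:
    """Excess cost of long-term sequelae among hospitalized cases.

    ``sequelae_profiles`` maps pathogen name to (sequela, probability among
    hospitalized, excess cost) triples; pathogens without profiles contribute
    nothing.
    """
    total: ArrayLike = 0.0
    for pathogen, triples in sequelae_profiles.items():
        if pathogen not in hospitalizations_by_pathogen:
            raise KeyError(f"sequelae profile references undeclared pathogen {pathogen!r}")
        hosp = hospitalizations_by_pathogen[pathogen]
        for _name, probability, excess in triples:
            total = total + hosp * probability * excess
    return total


def severity_cost(tier: Tier, **components: ArrayLike) -> CostBreakdown:
    """Assemble a tier's :class:`CostBreakdown`, enforcing tier composition.

    Components a tier does not incur (e.g. hospitalization for mild illness)
    must be absent or zero.
    """
    if tier not in _TIER_COMPONENTS:
        raise ValueError(f"invalid parameter: unknown tier {tier!r}")
    allowed = _TIER_COMPONENTS[tier]
    values: dict[str, ArrayLike] = {}
    for name, value in components.items():
        if name not in _COMPONENTS:
            raise ValueError(f"invalid parameter: unknown cost component {name!r}")
        if name not in allowed and np.any(np.asarray(value) != 0):
            raise ValueError(
                f"invalid parameter: component {name!r} must be zero in tier {tier!r}"
            )
        values[name] = value
    return CostBreakdown(tier=tier, **values)


def per_case_cost(total_cost: ArrayLike, n_cases: ArrayLike) -> ArrayLike:
    """Cost per case; requires a strictly positive case count."""
    if np.any(np.asarray(n_cases) <= 0):
        raise ValueError("no cases")
    return total_cost / n_cases
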