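"""Scenario configuration: the full parameter book for one burden estimate.

A scenario bundles everything the pipeline needs — census population bases,
per-activity participation and days-per-recreator, per-(activity, illness)
exposed/unexposed illness probabilities, severity and healthcare-utilization
profiles, pathogen surveillance records with underreporting multipliers, and
unit costs — with every uncertain quantity declared as a
:class:`~aquaburden.distributions.DistributionSpec`.

Scenario files are YAML (canonical) or JSON.  Any numeric field that accepts a
distribution also accepts a bare number, which is read as a point mass.
Unknown keys are rejected.  Proportions are truncated into [0, 1] and costs,
days and hours into [0, inf) at load time; truncation acts by clipping the
sampled draw, so one random variate is consumed per parameter per iteration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated, Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from .distributions import DistributionSpec, analytic_mean

__all__ = [
    "ScenarioError",
    "MalformedConfigError",
    "InvalidParameterError",
    "Illness",
    "ILLNESS_TYPES",
    "PopulationBase",
    "ActivityProfile",
    "IllnessRisk",
    "Utilization",
    "SeverityProfile",
    "SequelaProfile",
    "PathogenRecord",
    "CpiFactor",
    "TierSpecs",
    "CostInputs",
    "SimulationOptions",
    "ScenarioConfig",
    "read_scenario",
    "write_scenario",
    "packaged_scenario_path",
]


class ScenarioError(ValueError):
    """Base class for scenario loading/validation failures."""


class MalformedConfigError(ScenarioError):
    """The file could not be parsed as the documented schema."""


class InvalidParameterError(ScenarioError):
    """A parsed value violates a schema invariant."""


Illness = Literal["agi", "respiratory", "eye", "ear", "skin"]
ILLNESS_TYPES: tuple[Illness, ...] = ("agi", "respiratory", "eye", "ear", "skin")

CpiSeries = Literal["medical_commodities", "medical_services", "wages"]


def _coerce_spec(v):
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return DistributionSpec(family="point", value=float(v))
    return v


Spec = Annotated[DistributionSpec, BeforeValidator(_coerce_spec)]


def _central(spec: DistributionSpec) -> float:
    """Location used for sanity-range checks (before any clipping)."""
    if spec.family == "point":
        return spec.value
    if spec.family in ("normal", "truncated_normal", "lognormal"):
        return spec.mean
    if spec.family == "uniform":
        return 0.5 * (spec.low + spec.high)
    if spec.family in ("triangular", "pert"):
        return spec.mode
    return float(sum(spec.samples) / len(spec.samples))


def _as_proportion(spec: DistributionSpec, field: str) -> DistributionSpec:
    c = _central(spec)
    if not 0.0 <= c <= 1.0:
        raise InvalidParameterError(f"invalid parameter: {field} = {c} is not a proportion")
    return spec.clipped(0.0, 1.0)

def _as_nonnegative(spec: DistributionSpec, field: str) -> DistributionSpec:
    if _central(spec) < 0:
        raise InvalidParameterError(f"invalid parameter: {field} must be >= 0")
    return spec.clipped(0.0, None)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationBase(_Model):
    """Census population bases for the reference year."""

    adult_population: float = Field(gt=0, description="non-institutionalized, >= 16 y")
    child_population: float = Field(gt=0, description="< 16 y")
    reference_year: int


class ActivityProfile(_Model):
    """Participation and intensity of one water-recreation activity."""

    name: str
    participation_over16: Spec
    under16_share: Spec
    mean_days_per_year: Spec

    @model_validator(mode="after")
    def _domains(self) -> "ActivityProfile":
        object.__setattr__(
            self, "participation_over16",
            _as_proportion(self.participation_over16, f"{self.name}.participation_over16"),
        )
        object.__setattr__(
            self, "under16_share",
            _as_proportion(self.under16_share, f"{self.name}.under16_share"),
        )
        object.__setattr__(
            self, "mean_days_per_year",
            _as_nonnegative(self.mean_days_per_year, f"{self.name}.mean_days_per_year"),
        )
        return self


class IllnessRisk(_Model):
    """Exposed/unexposed illness probabilities for one (activity, illness).

    Pairs with no excess risk are simply absent from the scenario; an absent
    pair contributes zero cases and zero variance.
    """

    activity: str
    illness: Illness
    p_exposed: Spec
    p_unexposed: Spec

    @model_validator(mode="after")
    def _domains(self) -> "IllnessRisk":
        tag = f"{self.activity}/{self.illness}"
        object.__setattr__(self, "p_exposed", _as_proportion(self.p_exposed, f"{tag}.p_exposed"))
        object.__setattr__(
            self, "p_unexposed", _as_proportion(self.p_unexposed, f"{tag}.p_unexposed")
        )
        return self


class Utilization(_Model):
    """Per-case probabilities of medication use, visits, and work loss."""

    otc: Spec = DistributionSpec(family="point", value=0.0)
    rx: Spec = DistributionSpec(family="point", value=0.0)
    hcp: Spec = DistributionSpec(family="point", value=0.0)
    ed: Spec = DistributionSpec(family="point", value=0.0)
    work_loss: Spec = DistributionSpec(family="point", value=0.0)

    @model_validator(mode="after")
    def _domains(self) -> "Utilization":
        for f in ("otc", "rx", "hcp", "ed", "work_loss"):
            object.__setattr__(self, f, _as_proportion(getattr(self, f), f"utilization.{f}"))
        return self


class SeverityProfile(_Model):
    """Severity split and healthcare utilization for one illness type.

    ``moderate_fraction`` is the share of cases contacting a healthcare
    provider or emergency department (the moderate tier); the remainder are
    mild.  ``utilization`` applies to mild cases (and must therefore have no
    HCP/ED component); ``moderate_utilization`` applies to moderate cases and
    defaults to the mild probabilities with HCP contact certain.
    """

    illness: Illness
    moderate_fraction: Spec
    utilization: Utilization = Utilization()
    moderate_utilization: Optional[Utilization] = None

    @model_validator(mode="after")
    def _domains(self) -> "SeverityProfile":
        object.__setattr__(
            self, "moderate_fraction",
            _as_proportion(self.moderate_fraction, f"{self.illness}.moderate_fraction"),
        )
        for f in ("hcp", "ed"):
            if _central(getattr(self.utilization, f)) != 0.0:
                raise InvalidParameterError(
                    f"invalid parameter: {self.illness}.utilization.{f} must be 0 "
                    "(mild cases have no HCP/ED contact)"
                )
        return self

    def resolved_moderate_utilization(self) -> Utilization:
        if self.moderate_utilization is not None:
            return self.moderate_utilization
        u = self.utilization
        return Utilization(
            otc=u.otc, rx=u.rx, work_loss=u.work_loss,
            hcp=DistributionSpec(family="point", value=1.0),
            ed=DistributionSpec(family="point", value=0.0),
        )


class SequelaProfile(_Model):
    """A costed long-term consequence among hospitalized cases."""

    name: str
    probability: Spec
    excess_cost: Spec

    @model_validator(mode="after")
    def _domains(self) -> "SequelaProfile":
        object.__setattr__(
            self, "probability", _as_proportion(self.probability, f"{self.name}.probability")
        )
        object.__setattr__(
            self, "excess_cost", _as_nonnegative(self.excess_cost, f"{self.name}.excess_cost")
        )
        return self


class PathogenRecord(_Model):
    """Passive-surveillance counts and severe-outcome parameters.

    ``community_multiplier`` scales surveillance-detected cases to estimated
    community cases (25.5 in general; 1.1 for vibriosis, whose single cases
    are captured; 1.0 for Naegleria fowleri, which is essentially always
    diagnosed).  ``severe_correction`` is the doubling applied to
    hospitalizations and deaths for underdiagnosis of severe outcomes.
    """

    name: str
    observed_cases: Spec
    community_multiplier: float = 25.5
    hosp_fraction: Spec = DistributionSpec(family="point", value=0.0)
    death_fraction: Spec = DistributionSpec(family="point", value=0.0)
    severe_correction: float = 2.0
    hosp_cost: Spec = DistributionSpec(family="point", value=0.0)
    sequelae: list[SequelaProfile] = Field(default_factory=list)

    @model_validator(mode="after")
    def _domains(self) -> "PathogenRecord":
        if self.community_multiplier < 1.0:
            raise InvalidParameterError(
                f"invalid multiplier: {self.name}.community_multiplier < 1"
            )
        if self.severe_correction < 1.0:
            raise InvalidParameterError(
                f"invalid multiplier: {self.name}.severe_correction < 1"
            )
        object.__setattr__(
            self, "observed_cases",
            _as_nonnegative(self.observed_cases, f"{self.name}.observed_cases"),
        )
        object.__setattr__(
            self, "hosp_fraction",
            _as_proportion(self.hosp_fraction, f"{self.name}.hosp_fraction"),
        )
        object.__setattr__(
            self, "death_fraction",
            _as_proportion(self.death_fraction, f"{self.name}.death_fraction"),
        )
        object.__setattr__(
            self, "hosp_cost", _as_nonnegative(self.hosp_cost, f"{self.name}.hosp_cost")
        )
        return self


class CpiFactor(_Model):
    """Multiplicative factor converting one year/series into reference-year USD."""

    year: int
    series: CpiSeries
    factor: float = Field(gt=0)


class TierSpecs(_Model):
    """One DistributionSpec per severity tier (e.g. lost work hours)."""

    mild: Spec = DistributionSpec(family="point", value=0.0)
    moderate: Spec = DistributionSpec(family="point", value=0.0)
    severe: Spec = DistributionSpec(family="point", value=0.0)

    @model_validator(mode="after")
    def _domains(self) -> "TierSpecs":
        for f in ("mild", "moderate", "severe"):
            object.__setattr__(self, f, _as_nonnegative(getattr(self, f), f"lost_hours.{f}"))
        return self


class CostInputs(_Model):
    """Unit costs (reference-year USD), wages, VSL, and CPI factors."""

    otc_per_user: Spec
    rx_per_user: Spec
    hcp_visit: Spec
    ed_visit: Spec
    wage_per_hour: Spec
    lost_hours: TierSpecs = TierSpecs()
    severe_utilization: Utilization = Utilization()
    vsl: Spec = DistributionSpec(family="point", value=0.0)
    cpi_factors: list[CpiFactor] = Field(default_factory=list)

    @model_validator(mode="after")
    def _domains(self) -> "CostInputs":
        for f in ("otc_per_user", "rx_per_user", "hcp_visit", "ed_visit",
                  "wage_per_hour", "vsl"):
            object.__setattr__(self, f, _as_nonnegative(getattr(self, f), f"costs.{f}"))
        return self

    def cpi_factor(self, year: int, series: CpiSeries) -> float:
        for row in self.cpi_factors:
            if row.year == year and row.series == series:
                return row.factor
        raise KeyError(f"unknown CPI key: ({year}, {series})")


class SimulationOptions(_Model):
    truncate_negative_ar: bool = False
    n_iterations: int = Field(default=100_000, ge=1)
    seed: int = 42


class ScenarioConfig(_Model):
    """The complete, validated parameter book."""

    name: str = "scenario"
    population: PopulationBase
    activities: list[ActivityProfile]
    risks: list[IllnessRisk]
    severity: list[SeverityProfile]
    pathogens: list[PathogenRecord] = Field(default_factory=list)
    costs: CostInputs
    options: SimulationOptions = SimulationOptions()

    @model_validator(mode="after")
    def _cross_references(self) -> "ScenarioConfig":
        activity_names = [a.name for a in self.activities]
        if len(set(activity_names)) != len(activity_names):
            raise InvalidParameterError("invalid parameter: duplicate activity names")
        declared = set(activity_names)
        for r in self.risks:
            if r.activity not in declared:
                raise InvalidParameterError(
                    f"invalid parameter: risk references undeclared activity {r.activity!r}"
                )
        profiled = {s.illness for s in self.severity}
        if len(profiled) != len(self.severity):
            raise InvalidParameterError("invalid parameter: duplicate severity profiles")
        for r in self.risks:
            if r.illness not in profiled:
                raise InvalidParameterError(
                    f"invalid parameter: no severity profile for illness {r.illness!r}"
                )
        pairs = [(r.activity, r.illness) for r in self.risks]
        if len(set(pairs)) != len(pairs):
            raise InvalidParameterError("invalid parameter: duplicate (activity, illness) risk")
        names = [p.name for p in self.pathogens]
        if len(set(names)) != len(names):
            raise InvalidParameterError("invalid parameter: duplicate pathogen names")
        return self

    def severity_for(self, illness: str) -> SeverityProfile:
        for s in self.severity:
            if s.illness == illness:
                return s
        raise KeyError(illness)

    def illnesses(self) -> list[str]:
        """Illness types with at least one declared risk, in profile order."""
        used = {r.illness for r in self.risks}
        return [s.illness for s in self.severity if s.illness in used]


def _load_raw(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise MalformedConfigError(f"malformed config: {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise MalformedConfigError(f"malformed config: {path}: not a mapping")
    return raw


def read_scenario(path: str | Path) -> ScenarioConfig:
    """Read and validate a YAML/JSON scenario file.

    Raises :class:`MalformedConfigError` when the file does not parse and
    :class:`InvalidParameterError` (naming the offending field) when a value
    violates an invariant.
    """
    raw = _load_raw(path)
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise InvalidParameterError(
            f"invalid parameter: {loc}: {first['msg']}"
        ) from exc


def write_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a scenario to YAML (or JSON by extension); round-trips."""
    path = Path(path)
    payload = config.model_dump(exclude_none=True, mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def packaged_scenario_path(name: str = "us2007") -> Path:
    """Path to a scenario shipped with the package."""
    return Path(__file__).parent / "data" / f"{name}.yaml"
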