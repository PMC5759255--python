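"""Seeded Monte Carlo engine and result summaries.

A single iteration draws one value from every declared parameter
distribution, runs the exposure -> cases -> severe-outcome -> cost pipeline
on those values, and stores the realization.  Repeating this (100,000 times
by default) yields, for every output quantity, a mean and the central 90% of
values (C90): the empirical 5th and 95th percentiles, computed by linear
interpolation between order statistics.

Draw order is fixed and documented (activities, then risks, then severity
profiles, then pathogens, then cost inputs, each in declaration order; one
block of ``n`` variates per parameter), so a given (scenario, n, seed) is
bit-reproducible.  The same pipeline evaluated at the analytic mean of every
distribution gives the deterministic expectation; because every output is a
sum of products of independent draws, that evaluation is also the exact
expectation of the Monte Carlo mean.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Optional, Union

import numpy as np
import pandas as pd

from . import costs as cm
from . import exposure as ex
from . import severe as sv
from . import sporadic as sp
from .distributions import DistributionSpec, analytic_mean, sample
from .scenario import ScenarioConfig

__all__ = [
    "SummaryCell",
    "SimulationResult",
    "run_simulation",
    "expected_pipeline",
    "summarize",
    "render_tables",
]

ArrayLike = Union[float, np.ndarray]
Key = tuple[str, ...]


@dataclass(frozen=True)
class SummaryCell:
    """Mean and central-90% interval of one output over all draws."""

    mean: float
    p5: float
    p95: float
    n_draws: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mean, self.p5, self.p95)


def summarize(values) -> SummaryCell:
    """Mean and empirical 5th/95th percentiles (linear interpolation)."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("no draws")
    p5, p95 = np.percentile(arr, [5.0, 95.0])
    return SummaryCell(mean=float(arr.mean()), p5=float(p5), p95=float(p95), n_draws=arr.size)


# ---------------------------------------------------------------------------
# parameter traversal


def _spec_walk(scenario: ScenarioConfig) -> Iterator[tuple[Key, DistributionSpec]]:
    """Yield every sampleable parameter in the documented draw order."""
    for a in scenario.activities:
        yield ("activity", a.name, "participation_over16"), a.participation_over16
        yield ("activity", a.name, "under16_share"), a.under16_share
        yield ("activity", a.name, "mean_days_per_year"), a.mean_days_per_year
    for r in scenario.risks:
        yield ("risk", r.activity, r.illness, "p_exposed"), r.p_exposed
        yield ("risk", r.activity, r.illness, "p_unexposed"), r.p_unexposed
    for s in scenario.severity:
        yield ("severity", s.illness, "moderate_fraction"), s.moderate_fraction
        mu = s.utilization
        for f in ("otc", "rx", "work_loss"):
            yield ("severity", s.illness, "mild", f), getattr(mu, f)
        mo = s.resolved_moderate_utilization()
        for f in ("otc", "rx", "hcp", "ed", "work_loss"):
            yield ("severity", s.illness, "moderate", f), getattr(mo, f)
    for p in scenario.pathogens:
        yield ("pathogen", p.name, "observed_cases"), p.observed_cases
        yield ("pathogen", p.name, "hosp_fraction"), p.hosp_fraction
        yield ("pathogen", p.name, "death_fraction"), p.death_fraction
        yield ("pathogen", p.name, "hosp_cost"), p.hosp_cost
        for q in p.sequelae:
            yield ("pathogen", p.name, "sequela", q.name, "probability"), q.probability
            yield ("pathogen", p.name, "sequela", q.name, "excess_cost"), q.excess_cost
    c = scenario.costs
    yield ("costs", "otc_per_user"), c.otc_per_user
    yield ("costs", "rx_per_user"), c.rx_per_user
    yield ("costs", "hcp_visit"), c.hcp_visit
    yield ("costs", "ed_visit"), c.ed_visit
    yield ("costs", "wage_per_hour"), c.wage_per_hour
    for tier in ("mild", "moderate", "severe"):
        yield ("costs", "lost_hours", tier), getattr(c.lost_hours, tier)
    for f in ("otc", "rx", "hcp", "ed", "work_loss"):
        yield ("costs", "severe_utilization", f), getattr(c.severe_utilization, f)
    yield ("costs", "vsl"), c.vsl


# ---------------------------------------------------------------------------
# pipeline evaluation


@dataclass(frozen=True)
class SimulationResult:
    """All pipeline outputs, per draw (arrays) or as expectations (scalars)."""

    scenario_name: str
    n_draws: int
    seed: Optional[int]
    person_days: dict[str, ArrayLike]
    total_person_days: ArrayLike
    cases: dict[tuple[str, str], ArrayLike]
    illness_total: dict[str, ArrayLike]
    illness_mild: dict[str, ArrayLike]
    illness_moderate: dict[str, ArrayLike]
    total_cases: ArrayLike
    mild_cases: ArrayLike
    moderate_cases: ArrayLike
    moderate_share: ArrayLike
    community_cases: dict[str, ArrayLike]
    hospitalizations: dict[str, ArrayLike]
    deaths: dict[str, ArrayLike]
    total_hospitalizations: ArrayLike
    total_deaths: ArrayLike
    tiers: dict[str, cm.CostBreakdown]
    grand_total: ArrayLike
    per_case: dict[str, ArrayLike]

    caseloads: list[sp.CaseLoad]

    def summary(self) -> dict:
        """Nested mapping of SummaryCells for every reported quantity."""
        s = summarize

        def dmap(d):
            return {k if isinstance(k, str) else "/".join(k): s(v) for k, v in d.items()}

        return {
            "person_days": dmap(self.person_days),
            "total_person_days": s(self.total_person_days),
            "cases": dmap(self.cases),
            "illness_total": dmap(self.illness_total),
            "illness_mild": dmap(self.illness_mild),
            "illness_moderate": dmap(self.illness_moderate),
            "total_cases": s(self.total_cases),
            "mild_cases": s(self.mild_cases),
            "moderate_cases": s(self.moderate_cases),
            "moderate_share": s(self.moderate_share),
            "total_hospitalizations": s(self.total_hospitalizations),
            "total_deaths": s(self.total_deaths),
            "tiers": {
                tier: {**{k: s(v) for k, v in bd.components().items()}, "total": s(bd.total)}
                for tier, bd in self.tiers.items()
            },
            "grand_total": s(self.grand_total),
            "per_case": {
                k: s(np.atleast_1d(np.asarray(v, dtype=float))[
                    np.isfinite(np.atleast_1d(np.asarray(v, dtype=float)))
                ])
                for k, v in self.per_case.items()
            },
        }


def _evaluate(
    scenario: ScenarioConfig,
    value: Callable[[Key], ArrayLike],
    n_draws: int,
    seed: Optional[int],
) -> SimulationResult:
    pop = scenario.population
    truncate = scenario.options.truncate_negative_ar

    exposures: dict[str, ex.ActivityExposure] = {}
    for a in scenario.activities:
        r16 = ex.recreators_over16(
            value(("activity", a.name, "participation_over16")), pop.adult_population
        )
        ru16 = ex.recreators_under16(
            value(("activity", a.name, "under16_share")), pop.child_population
        )
        pd_a = ex.person_days(r16 + ru16, value(("activity", a.name, "mean_days_per_year")))
        exposures[a.name] = ex.ActivityExposure(a.name, r16, ru16, pd_a)
    person_days = {name: e.person_days for name, e in exposures.items()}
    total_person_days = ex.total_events(exposures.values())

    cases: dict[tuple[str, str], ArrayLike] = {}
    for r in scenario.risks:
        ar = sp.attributable_risk(
            value(("risk", r.activity, r.illness, "p_exposed")),
            value(("risk", r.activity, r.illness, "p_unexposed")),
            truncate_at_zero=truncate,
        )
        cases[(r.activity, r.illness)] = sp.expected_cases(person_days[r.activity], ar)

    illnesses = scenario.illnesses()
    mod_frac = {ill: value(("severity", ill, "moderate_fraction")) for ill in illnesses}
    caseloads: list[sp.CaseLoad] = []
    for (act, ill), total in cases.items():
        mild, moderate = sp.split_severity(total, mod_frac[ill])
        caseloads.append(sp.CaseLoad(act, ill, total, mild, moderate))
    illness_total = {
        ill: sum(c.total_cases for c in caseloads if c.illness == ill) for ill in illnesses
    }
    illness_mild = {
        ill: sum(c.mild_cases for c in caseloads if c.illness == ill) for ill in illnesses
    }
    illness_moderate = {
        ill: sum(c.moderate_cases for c in caseloads if c.illness == ill) for ill in illnesses
    }
    total_cases = sum(illness_total.values())
    mild_cases = sum(illness_mild.values())
    moderate_cases = sum(illness_moderate.values())
    moderate_share = sp.moderate_share_overall(caseloads)

    community: dict[str, ArrayLike] = {}
    hosp: dict[str, ArrayLike] = {}
    deaths: dict[str, ArrayLike] = {}
    for p in scenario.pathogens:
        cc = sv.adjust_for_underreporting(
            value(("pathogen", p.name, "observed_cases")), p.community_multiplier
        )
        out = sv.severe_outcomes(
            cc,
            value(("pathogen", p.name, "hosp_fraction")),
            value(("pathogen", p.name, "death_fraction")),
            p.severe_correction,
            pathogen=p.name,
        )
        community[p.name] = cc
        hosp[p.name] = out.hospitalizations
        deaths[p.name] = out.deaths
    total_hosp, total_deaths = sv.aggregate_severe(
        sv.SevereOutcome(n, community[n], hosp[n], deaths[n]) for n in community
    )

    # --- costs (Eq. per-tier composition) --------------------------------
    c_otc = value(("costs", "otc_per_user"))
    c_rx = value(("costs", "rx_per_user"))
    c_hcp = value(("costs", "hcp_visit"))
    c_ed = value(("costs", "ed_visit"))
    wage = value(("costs", "wage_per_hour"))

    def tier_sum(per_illness: dict[str, ArrayLike], tier_key: str, field: str) -> ArrayLike:
        return sum(
            per_illness[ill] * value(("severity", ill, tier_key, field)) for ill in illnesses
        )

    mild_bd = cm.severity_cost(
        "mild",
        otc=cm.component_cost(tier_sum(illness_mild, "mild", "otc"), 1.0, c_otc),
        rx=cm.component_cost(tier_sum(illness_mild, "mild", "rx"), 1.0, c_rx),
        productivity=cm.productivity_cost(
            tier_sum(illness_mild, "mild", "work_loss"),
            1.0,
            value(("costs", "lost_hours", "mild")),
            wage,
        ),
    )
    moderate_bd = cm.severity_cost(
        "moderate",
        otc=cm.component_cost(tier_sum(illness_moderate, "moderate", "otc"), 1.0, c_otc),
        rx=cm.component_cost(tier_sum(illness_moderate, "moderate", "rx"), 1.0, c_rx),
        hcp=cm.component_cost(tier_sum(illness_moderate, "moderate", "hcp"), 1.0, c_hcp),
        ed=cm.component_cost(tier_sum(illness_moderate, "moderate", "ed"), 1.0, c_ed),
        productivity=cm.productivity_cost(
            tier_sum(illness_moderate, "moderate", "work_loss"),
            1.0,
            value(("costs", "lost_hours", "moderate")),
            wage,
        ),
    )
    hospital_cost = sum(
        (hosp[p.name] * value(("pathogen", p.name, "hosp_cost")) for p in scenario.pathogens),
        start=0.0,
    )
    seq_cost = cm.sequelae_cost(
        hosp,
        {
            p.name: [
                (
                    q.name,
                    value(("pathogen", p.name, "sequela", q.name, "probability")),
                    value(("pathogen", p.name, "sequela", q.name, "excess_cost")),
                )
                for q in p.sequelae
            ]
            for p in scenario.pathogens
            if p.sequelae
        },
    )
    su = lambda f: value(("costs", "severe_utilization", f))
    severe_bd = cm.severity_cost(
        "severe",
        otc=cm.component_cost(total_hosp, su("otc"), c_otc),
        rx=cm.component_cost(total_hosp, su("rx"), c_rx),
        hcp=cm.component_cost(total_hosp, su("hcp"), c_hcp),
        ed=cm.component_cost(total_hosp, su("ed"), c_ed),
        hospital=hospital_cost,
        death_vsl=cm.mortality_cost(total_deaths, value(("costs", "vsl"))),
        sequelae=seq_cost,
        productivity=cm.productivity_cost(
            total_hosp, su("work_loss"), value(("costs", "lost_hours", "severe")), wage
        ),
    )
    tiers = {"mild": mild_bd, "moderate": moderate_bd, "severe": severe_bd}
    grand_total = mild_bd.total + moderate_bd.total + severe_bd.total

    def safe_ratio(cost: ArrayLike, n: ArrayLike) -> ArrayLike:
        n_arr = np.asarray(n, dtype=float)
        c_arr = np.asarray(cost, dtype=float)
        out = np.divide(c_arr, n_arr, out=np.full_like(n_arr + c_arr, np.nan), where=n_arr > 0)
        return float(out) if out.ndim == 0 else out

    severe_case_count = total_hosp + total_deaths
    per_case = {
        "mild": safe_ratio(mild_bd.total, mild_cases),
        "moderate": safe_ratio(moderate_bd.total, moderate_cases),
        "severe": safe_ratio(severe_bd.total, severe_case_count),
    }

    return SimulationResult(
        scenario_name=scenario.name,
        n_draws=n_draws,
        seed=seed,
        person_days=person_days,
        total_person_days=total_person_days,
        cases=cases,
        caseloads=caseloads,
        illness_total=illness_total,
        illness_mild=illness_mild,
        illness_moderate=illness_moderate,
        total_cases=total_cases,
        mild_cases=mild_cases,
        moderate_cases=moderate_cases,
        moderate_share=moderate_share,
        community_cases=community,
        hospitalizations=hosp,
        deaths=deaths,
        total_hospitalizations=total_hosp,
        total_deaths=total_deaths,
        tiers=tiers,
        grand_total=grand_total,
        per_case=per_case,
    )


def run_simulation(
    scenario: ScenarioConfig,
    n_iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Run the full pipeline for ``n_iterations`` seeded Monte Carlo draws."""
    n = scenario.options.n_iterations if n_iterations is None else int(n_iterations)
    if n < 1:
        raise ValueError("invalid parameter: n_iterations must be >= 1")
    s = scenario.options.seed if seed is None else int(seed)
    rng = np.random.default_rng(s)
    draws = {key: sample(spec, rng, size=n) for key, spec in _spec_walk(scenario)}
    return _evaluate(scenario, lambda key: draws[key], n_draws=n, seed=s)


def expected_pipeline(scenario: ScenarioConfig) -> SimulationResult:
    """Evaluate the pipeline at the analytic mean of every distribution.

    Because every reported quantity (other than the per-case ratios) is a sum
    of products of independent parameters, this equals the exact expectation
    of the corresponding Monte Carlo output.  Requires the negative-AR
    truncation switch to be off, since truncation breaks that multilinearity.
    """
    if scenario.options.truncate_negative_ar:
        raise ValueError(
            "invalid parameter: expected_pipeline requires truncate_negative_ar=False"
        )
    means = {key: analytic_mean(spec) for key, spec in _spec_walk(scenario)}
    return _evaluate(scenario, lambda key: means[key], n_draws=0, seed=None)


# ---------------------------------------------------------------------------
# report rendering


def _fmt_cell(cell: SummaryCell, scale: float = 1.0, digits: int = 2) -> str:
    return (
        f"{cell.mean / scale:.{digits}f} "
        f"({cell.p5 / scale:.{digits}f}-{cell.p95 / scale:.{digits}f})"
    )


def _cell_dict(cell: SummaryCell) -> dict:
    return {"mean": cell.mean, "p5": cell.p5, "p95": cell.p95, "n_draws": cell.n_draws}


def _summary_json(summary: dict):
    if isinstance(summary, SummaryCell):
        return _cell_dict(summary)
    return {k: _summary_json(v) for k, v in summary.items()}


def render_tables(
    result: SimulationResult, scenario: ScenarioConfig, outdir: str | Path
) -> list[Path]:
    """Write exposure/case/cost tables (CSV), a JSON summary, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = summarize
    written: list[Path] = []

    # exposure table: recreators and person-days per activity
    rows = []
    for a in scenario.activities:
        pd_cell = s(result.person_days[a.name])
        rows.append(
            {
                "activity": a.name,
                "person_days_mean": pd_cell.mean,
                "person_days_p5": pd_cell.p5,
                "person_days_p95": pd_cell.p95,
            }
        )
    total = s(result.total_person_days)
    rows.append(
        {
            "activity": "total",
            "person_days_mean": total.mean,
            "person_days_p5": total.p5,
            "person_days_p95": total.p95,
        }
    )
    path = outdir / "exposure_table.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    # case table: activity x illness means with C90, plus moderate share row
    illnesses = scenario.illnesses()
    case_rows = []
    for a in scenario.activities:
        row: dict = {"activity": a.name}
        for ill in illnesses:
            key = (a.name, ill)
            row[ill] = _fmt_cell(s(result.cases[key]), 1e6) if key in result.cases else "--"
        case_rows.append(row)
    total_row: dict = {"activity": "total"}
    mod_row: dict = {"activity": "moderate_fraction"}
    for ill in illnesses:
        total_row[ill] = _fmt_cell(s(result.illness_total[ill]), 1e6)
        mod_share = s(result.illness_moderate[ill]).mean / s(result.illness_total[ill]).mean
        mod_row[ill] = f"{100 * mod_share:.1f}%"
    case_rows += [total_row, mod_row]
    path = outdir / "case_table.csv"
    pd.DataFrame(case_rows).to_csv(path, index=False)
    written.append(path)

    # cost table: component x tier, in millions of USD
    comp_rows = []
    for comp in ("otc", "rx", "hcp", "ed", "hospital", "death_vsl", "sequelae", "productivity"):
        row = {"component": comp}
        for tier, bd in result.tiers.items():
            v = bd.components()[comp]
            row[tier] = _fmt_cell(s(v), 1e6) if np.any(np.asarray(v) != 0) else "--"
        comp_rows.append(row)
    comp_rows.append(
        {"component": "total", **{t: _fmt_cell(s(bd.total), 1e6) for t, bd in result.tiers.items()}}
    )
    path = outdir / "cost_table.csv"
    pd.DataFrame(comp_rows).to_csv(path, index=False)
    written.append(path)

    path = outdir / "summary.json"
    path.write_text(json.dumps(_summary_json(result.summary()), indent=2))
    written.append(path)

    config_hash = hashlib.sha256(
        json.dumps(scenario.model_dump(mode="json"), sort_keys=True).encode()
    ).hexdigest()
    path = outdir / "run_manifest.txt"
    path.write_text(
        f"scenario: {scenario.name}\n"
        f"n_iterations: {result.n_draws}\n"
        f"seed: {result.seed}\n"
        f"config_sha256: {config_hash}\n"
    )
    written.append(path)
    return written
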