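import numpy as np
import pytest

from aquaburden import (
    DistributionSpec,
    packaged_scenario_path,
    point,
    read_scenario,
    run_simulation,
)
from aquaburden.scenario import (
    ActivityProfile,
    CostInputs,
    CpiFactor,
    IllnessRisk,
    PathogenRecord,
    PopulationBase,
    ScenarioConfig,
    SequelaProfile,
    SeverityProfile,
    SimulationOptions,
    TierSpecs,
    Utilization,
)


@pytest.fixture(scope="session")
def us2007():
    return read_scenario(packaged_scenario_path("us2007"))


@pytest.fixture(scope="session")
def us2007_run(us2007):
    """One shared full-size Monte Carlo run of the packaged 2007 scenario."""
    return run_simulation(us2007, n_iterations=100_000, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def point_scenario():
    """A small scenario whose every parameter is a point mass."""
    return ScenarioConfig(
        name="point-mass",
        population=PopulationBase(
            adult_population=2e8, child_population=5e7, reference_year=2007
        ),
        activities=[
            ActivityProfile(
                name="swimming",
                participation_over16=point(0.4),
                under16_share=point(0.8),
                mean_days_per_year=point(10.0),
            ),
            ActivityProfile(
                name="fishing",
                participation_over16=point(0.2),
                under16_share=point(0.3),
                mean_days_per_year=point(12.0),
            ),
        ],
        risks=[
            IllnessRisk(
                activity="swimming", illness="agi",
                p_exposed=point(0.04), p_unexposed=point(0.025),
            ),
            IllnessRisk(
                activity="fishing", illness="agi",
                p_exposed=point(0.05), p_unexposed=point(0.038),
            ),
            IllnessRisk(
                activity="swimming", illness="ear",
                p_exposed=point(0.016), p_unexposed=point(0.012),
            ),
        ],
        severity=[
            SeverityProfile(
                illness="agi",
                moderate_fraction=point(0.072),
                utilization=Utilization(otc=point(0.5), rx=point(0.02), work_loss=point(0.1)),
                moderate_utilization=Utilization(
                    otc=point(0.6), rx=point(0.3), hcp=point(0.9), ed=point(0.1),
                    work_loss=point(0.5),
                ),
            ),
            SeverityProfile(
                illness="ear",
                moderate_fraction=point(0.243),
                utilization=Utilization(otc=point(0.4), rx=point(0.01), work_loss=point(0.05)),
            ),
        ],
        pathogens=[
            PathogenRecord(
                name="ecoli_o157",
                observed_cases=point(10.0),
                community_multiplier=25.5,
                hosp_fraction=point(0.3),
                death_fraction=point(0.01),
                severe_correction=2.0,
                hosp_cost=point(9000.0),
                sequelae=[
                    SequelaProfile(
                        name="hus", probability=point(0.1), excess_cost=point(20000.0)
                    )
                ],
            ),
            PathogenRecord(
                name="naegleria_fowleri",
                observed_cases=point(4.0),
                community_multiplier=1.0,
                hosp_fraction=point(1.0),
                death_fraction=point(0.99),
                severe_correction=2.0,
                hosp_cost=point(12000.0),
            ),
        ],
        costs=CostInputs(
            otc_per_user=point(6.0),
            rx_per_user=point(45.0),
            hcp_visit=point(80.0),
            ed_visit=point(800.0),
            wage_per_hour=point(19.0),
            lost_hours=TierSpecs(mild=point(3.0), moderate=point(2.5), severe=point(20.0)),
            severe_utilization=Utilization(
                otc=point(0.8), rx=point(0.8), hcp=point(1.0), ed=point(0.35),
                work_loss=point(1.0),
            ),
            vsl=point(7.4e6),
            cpi_factors=[CpiFactor(year=2007, series="medical_services", factor=1.0)],
        ),
        options=SimulationOptions(truncate_negative_ar=False, n_iterations=10, seed=7),
    )
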