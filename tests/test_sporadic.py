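import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaburden.simulation import run_simulation
from aquaburden.sporadic import (
    CaseLoad,
    attributable_risk,
    expected_cases,
    moderate_share_overall,
    split_severity,
)

# published total sporadic cases (millions) and moderate-severity fractions
PUBLISHED_CASE_TOTALS = {
    "agi": 50.95, "respiratory": 9.22, "eye": 7.55, "ear": 6.87, "skin": 12.06
}
MODERATE_FRACTIONS = {
    "agi": 0.072, "respiratory": 0.137, "eye": 0.104, "ear": 0.243, "skin": 0.054
}


class TestAttributableRisk:
    @pytest.mark.parametrize(
        "p_exposed, p_unexposed, expected",
        [
            (0.040, 0.025, 0.015),  # swimming AGI
            (0.053, 0.038, 0.015),  # fishing AGI
            (0.040, 0.034, 0.006),  # other incidental-contact AGI
        ],
    )
    def test_cohort_risk_differences(self, p_exposed, p_unexposed, expected):
        assert attributable_risk(p_exposed, p_unexposed) == pytest.approx(expected, abs=1e-12)

    def test_equal_risks_give_zero(self):
        assert attributable_risk(0.07, 0.07) == 0.0

    def test_truncation_floors_negative_risk(self):
        assert attributable_risk(0.02, 0.05) == pytest.approx(-0.03)
        assert attributable_risk(0.02, 0.05, truncate_at_zero=True) == 0.0


class TestExpectedCases:
    def test_swimming_agi_point_product(self):
        assert expected_cases(1928.9e6, 0.015) == pytest.approx(28.93e6, rel=1e-3)

    def test_fishing_agi_inside_published_interval(self):
        cases = expected_cases(1105.1e6, 0.015)
        assert 4.12e6 < cases < 25.12e6

    def test_zero_events_zero_cases(self):
        assert expected_cases(0.0, 0.015) == 0.0

    def test_negative_ar_propagates(self):
        assert expected_cases(1e9, -0.002) == pytest.approx(-2e6)

    def test_negative_person_days_rejected(self):
        with pytest.raises(ValueError, match="invalid parameter"):
            expected_cases(-1.0, 0.01)

    @settings(max_examples=50, derandomize=True)
    @given(
        pd1=st.floats(0, 1e10), pd2=st.floats(0, 1e10),
        ar1=st.floats(-0.05, 0.05), ar2=st.floats(-0.05, 0.05),
    )
    def test_monotone_in_events_and_risk(self, pd1, pd2, ar1, ar2):
        lo_pd, hi_pd = sorted((pd1, pd2))
        lo_ar, hi_ar = sorted((ar1, ar2))
        if lo_ar >= 0:
            assert expected_cases(lo_pd, lo_ar) <= expected_cases(hi_pd, lo_ar)
        assert expected_cases(hi_pd, lo_ar) <= expected_cases(hi_pd, hi_ar)


class TestSplitSeverity:
    def test_published_agi_split(self):
        mild, moderate = split_severity(50.95e6, 0.072)
        assert moderate == pytest.approx(3.67e6, rel=2e-3)
        assert mild == pytest.approx(47.28e6, rel=2e-3)

    def test_all_mild_and_all_moderate_edges(self):
        assert split_severity(10.0, 0.0) == (10.0, 0.0)
        mild, moderate = split_severity(10.0, 1.0)
        assert (mild, moderate) == (0.0, 10.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid parameter"):
            split_severity(10.0, 1.2)

    @settings(max_examples=100, derandomize=True)
    @given(total=st.floats(-1e9, 1e9), frac=st.floats(0, 1))
    def test_case_conservation(self, total, frac):
        mild, moderate = split_severity(total, frac)
        assert mild + moderate == pytest.approx(total, rel=1e-12, abs=1e-9)


class TestModerateShareOverall:
    def test_published_totals_give_nine_percent(self):
        loads = []
        for ill, total in PUBLISHED_CASE_TOTALS.items():
            mild, moderate = split_severity(total * 1e6, MODERATE_FRACTIONS[ill])
            loads.append(CaseLoad("all", ill, total * 1e6, mild, moderate))
        share = moderate_share_overall(loads)
        assert share == pytest.approx(0.0927, abs=5e-4)

    def test_single_illness_returns_its_fraction(self):
        loads = [CaseLoad("a", "agi", 100.0, 90.0, 10.0)]
        assert moderate_share_overall(loads) == pytest.approx(0.1)

    def test_zero_moderate_gives_zero_share(self):
        loads = [CaseLoad("a", "agi", 100.0, 100.0, 0.0)]
        assert moderate_share_overall(loads) == 0.0

    def test_no_cases_raises(self):
        with pytest.raises(ValueError, match="no cases"):
            moderate_share_overall([CaseLoad("a", "agi", 0.0, 0.0, 0.0)])


class TestTruncationSensitivity:
    def test_truncation_never_decreases_cases_and_barely_moves_cost(self, us2007):
        """Flooring negative AR draws raises mean cases; cost shift is small."""
        n, seed = 20_000, 7
        base = run_simulation(us2007, n_iterations=n, seed=seed)
        truncated_scenario = us2007.model_copy(
            update={"options": us2007.options.model_copy(
                update={"truncate_negative_ar": True})}
        )
        trunc = run_simulation(truncated_scenario, n_iterations=n, seed=seed)
        assert trunc.total_cases.mean() >= base.total_cases.mean()
        # identical seed: truncation only ever raises a given draw
        assert np.all(trunc.total_cases >= base.total_cases - 1e-6)
        rel_change = abs(trunc.grand_total.mean() - base.grand_total.mean())
        assert rel_change / base.grand_total.mean() < 0.05


def test_absent_pairs_contribute_no_cases_or_variance(us2007, us2007_run):
    declared = {(r.activity, r.illness) for r in us2007.risks}
    assert ("fishing", "respiratory") not in declared  # no excess risk published
    assert set(us2007_run.cases) == declared
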