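import json

import numpy as np
import pytest

from aquaburden.simulation import (
    expected_pipeline,
    render_tables,
    run_simulation,
    summarize,
)
from aquaburden.synthetic import flatten_result


class TestSummarize:
    def test_constant_list_collapses(self):
        cell = summarize([3.0] * 50)
        assert (cell.mean, cell.p5, cell.p95) == (3.0, 3.0, 3.0)
        assert cell.n_draws == 50

    def test_linear_interpolation_on_1_to_100(self):
        cell = summarize(np.arange(1, 101, dtype=float))
        assert cell.mean == pytest.approx(50.5)
        assert cell.p5 == pytest.approx(5.95)
        assert cell.p95 == pytest.approx(95.05)

    def test_standard_normal_quantile(self, rng):
        cell = summarize(rng.standard_normal(100_000))
        assert cell.p5 == pytest.approx(-1.645, abs=0.03)
        assert cell.p95 == pytest.approx(1.645, abs=0.03)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no draws"):
            summarize([])


class TestDeterminism:
    def test_identical_seed_reproduces_draws_exactly(self, us2007):
        a = run_simulation(us2007, n_iterations=500, seed=11)
        b = run_simulation(us2007, n_iterations=500, seed=11)
        np.testing.assert_array_equal(a.grand_total, b.grand_total)
        np.testing.assert_array_equal(a.total_cases, b.total_cases)
        np.testing.assert_array_equal(a.total_deaths, b.total_deaths)

    def test_different_seeds_differ(self, us2007):
        a = run_simulation(us2007, n_iterations=500, seed=11)
        b = run_simulation(us2007, n_iterations=500, seed=12)
        assert not np.array_equal(a.grand_total, b.grand_total)

    def test_scenario_default_seed_used_when_unspecified(self, us2007):
        a = run_simulation(us2007, n_iterations=200)
        b = run_simulation(us2007, n_iterations=200, seed=us2007.options.seed)
        np.testing.assert_array_equal(a.grand_total, b.grand_total)


class TestPointMassOracle:
    def test_all_draws_identical(self, point_scenario):
        res = run_simulation(point_scenario, n_iterations=10, seed=3)
        for cell, values in flatten_result(res).items():
            arr = np.atleast_1d(values)
            assert np.all(arr == arr[0]), cell

    def test_monte_carlo_equals_deterministic_exactly(self, point_scenario):
        """With every distribution degenerate, the simulated summary equals
        the single deterministic pipeline evaluation bit for bit."""
        mc = flatten_result(run_simulation(point_scenario, n_iterations=10, seed=3))
        det = flatten_result(expected_pipeline(point_scenario))
        for cell, values in mc.items():
            assert np.all(np.atleast_1d(values) == det[cell]), cell

    def test_single_iteration_allowed(self, point_scenario):
        res = run_simulation(point_scenario, n_iterations=1, seed=0)
        assert np.atleast_1d(res.grand_total).size == 1


class TestConservation:
    def test_grand_total_is_tier_sum_per_draw(self, us2007_run):
        tier_sum = sum(bd.total for bd in us2007_run.tiers.values())
        np.testing.assert_allclose(us2007_run.grand_total, tier_sum, rtol=1e-12)

    def test_tier_total_is_component_sum_per_draw(self, us2007_run):
        for tier, bd in us2007_run.tiers.items():
            comp_sum = sum(bd.components().values())
            np.testing.assert_allclose(bd.total, comp_sum, rtol=1e-12, err_msg=tier)

    def test_mild_and_moderate_conserve_total_cases(self, us2007_run):
        np.testing.assert_allclose(
            us2007_run.mild_cases + us2007_run.moderate_cases,
            us2007_run.total_cases,
            rtol=1e-10,
        )

    def test_tier_composition_zeroes(self, us2007_run):
        mild = us2007_run.tiers["mild"]
        assert np.all(np.asarray(mild.hcp) == 0) and np.all(np.asarray(mild.ed) == 0)
        assert np.all(np.asarray(mild.hospital) == 0)
        assert np.all(np.asarray(mild.death_vsl) == 0)
        moderate = us2007_run.tiers["moderate"]
        assert np.all(np.asarray(moderate.hospital) == 0)
        assert np.all(np.asarray(moderate.death_vsl) == 0)
        assert np.all(np.asarray(moderate.sequelae) == 0)


def test_convergence_of_grand_total_mean(us2007):
    small = run_simulation(us2007, n_iterations=10_000, seed=5)
    large = run_simulation(us2007, n_iterations=100_000, seed=6)
    se = small.grand_total.std(ddof=1) / np.sqrt(10_000)
    assert abs(small.grand_total.mean() - large.grand_total.mean()) < 4 * se


class TestRenderTables:
    def test_files_written_and_json_round_trips(self, us2007, tmp_path):
        res = run_simulation(us2007, n_iterations=300, seed=1)
        outdir = tmp_path / "made" / "on" / "demand"
        written = render_tables(res, us2007, outdir)
        names = {p.name for p in written}
        assert names == {
            "exposure_table.csv", "case_table.csv", "cost_table.csv",
            "summary.json", "run_manifest.txt",
        }
        payload = json.loads((outdir / "summary.json").read_text())
        grand = res.summary()["grand_total"]
        assert payload["grand_total"]["mean"] == pytest.approx(grand.mean)
        assert payload["grand_total"]["p5"] == pytest.approx(grand.p5)
        manifest = (outdir / "run_manifest.txt").read_text()
        assert "seed: 1" in manifest and "n_iterations: 300" in manifest
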