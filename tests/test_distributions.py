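import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aquaburden.distributions import (
    DistributionSpec,
    Z90,
    analytic_mean,
    point,
    sample,
    spec_from_c90,
    spec_from_ci95,
)

ALL_FAMILY_SPECS = [
    point(5.0),
    DistributionSpec(family="uniform", low=2.0, high=8.0),
    DistributionSpec(family="normal", mean=10.0, sd=2.0),
    DistributionSpec(family="truncated_normal", mean=0.015, sd=0.003, lower_bound=0.0),
    DistributionSpec(family="triangular", min=1.0, mode=3.0, max=9.0),
    DistributionSpec(family="pert", min=1.0, mode=3.0, max=9.0),
    DistributionSpec(family="lognormal", mean=7.4e6, sigma_log=0.55),
    DistributionSpec(family="empirical", samples=(1.0, 2.0, 2.0, 7.0)),
    # clipped variants where the bound actually bites
    DistributionSpec(family="normal", mean=0.95, sd=0.05, lower_bound=0.0, upper_bound=1.0),
    DistributionSpec(family="uniform", low=-1.0, high=3.0, lower_bound=0.0),
]


def test_point_mass_returns_value_for_any_rng(rng):
    spec = point(5.0)
    assert sample(spec, rng) == 5.0
    assert np.all(sample(spec, rng, size=100) == 5.0)
    assert analytic_mean(spec) == 5.0


def test_truncated_normal_draws_respect_lower_bound(rng):
    spec = DistributionSpec(
        family="truncated_normal", mean=0.015, sd=0.003, lower_bound=0.0
    )
    draws = sample(spec, rng, size=50_000)
    assert np.all(draws >= 0.0)


def test_normal_mean_converges_at_clt_rate(rng):
    spec = DistributionSpec(family="normal", mean=10.0, sd=2.0)
    draws = sample(spec, rng, size=100_000)
    assert abs(draws.mean() - 10.0) < 3 * 2.0 / math.sqrt(100_000)


@pytest.mark.parametrize("spec", ALL_FAMILY_SPECS, ids=lambda s: s.family + ("+clip" if s.lower_bound is not None or s.upper_bound is not None else ""))
def test_empirical_mean_matches_analytic_mean(spec, rng):
    """10^5 draws of every family land within 4 standard errors of E[X]."""
    n = 100_000
    draws = sample(spec, rng, size=n)
    se = draws.std(ddof=1) / math.sqrt(n)
    tol = 4 * se if se > 0 else 1e-12
    assert abs(draws.mean() - analytic_mean(spec)) < tol


def test_draws_stay_inside_declared_bounds(rng):
    spec = DistributionSpec(family="normal", mean=0.5, sd=1.0, lower_bound=0.0, upper_bound=1.0)
    draws = sample(spec, rng, size=10_000)
    assert draws.min() >= 0.0 and draws.max() <= 1.0


def test_sampling_is_reproducible_bit_for_bit():
    spec = DistributionSpec(family="pert", min=1.0, mode=3.0, max=9.0)
    a = sample(spec, np.random.default_rng(99), size=1000)
    b = sample(spec, np.random.default_rng(99), size=1000)
    np.testing.assert_array_equal(a, b)


class TestSpecFromC90:
    def test_reported_mean_and_interval_are_reproduced(self):
        # mean and C90 of a reported per-case cost
        spec = spec_from_c90(9.50, 8.62, 10.34)
        assert spec.family == "normal"
        assert spec.mean == 9.50
        assert spec.sd == pytest.approx(0.5229, abs=5e-4)
        q5, q95 = stats.norm(spec.mean, spec.sd).ppf([0.05, 0.95])
        assert q5 == pytest.approx(8.64, abs=0.05)
        assert q95 == pytest.approx(10.36, abs=0.05)

    def test_zero_width_interval_collapses_to_point(self):
        assert spec_from_c90(5.0, 5.0, 5.0) == point(5.0)

    def test_unordered_inputs_rejected(self):
        with pytest.raises(ValueError, match="invalid C90"):
            spec_from_c90(10.0, 12.0, 8.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        mean=st.floats(-50, 50),
        half=st.floats(0.1, 20),
    )
    def test_untruncated_quantiles_invert_construction(self, mean, half):
        spec = spec_from_c90(mean, mean - half, mean + half)
        q5, q95 = stats.norm(spec.mean, spec.sd).ppf([0.05, 0.95])
        assert q5 == pytest.approx(mean - half, rel=1e-6, abs=1e-6)
        assert q95 == pytest.approx(mean + half, rel=1e-6, abs=1e-6)


def test_ci95_uses_wider_z_than_c90():
    c90 = spec_from_c90(0.04, 0.036, 0.044)
    ci95 = spec_from_ci95(0.04, 0.036, 0.044)
    assert ci95.sd < c90.sd
    assert ci95.sd == pytest.approx((0.044 - 0.036) / (2 * 1.959964), rel=1e-4)


def test_clipped_normal_analytic_mean_matches_simulation(rng):
    # lower clip at zero pushes the mean up; closed form vs brute force
    spec = DistributionSpec(family="normal", mean=0.01, sd=0.02, lower_bound=0.0)
    draws = sample(spec, rng, size=400_000)
    se = draws.std(ddof=1) / math.sqrt(draws.size)
    assert abs(analytic_mean(spec) - draws.mean()) < 5 * se
    assert analytic_mean(spec) > 0.01


@pytest.mark.parametrize(
    "kwargs, message",
    [
        (dict(family="point"), "requires 'value'"),
        (dict(family="normal", mean=1.0, sd=0.0), "strictly positive"),
        (dict(family="normal", mean=1.0), "exactly one of"),
        (dict(family="normal", mean=1.0, sd=0.1, c90=(0.9, 1.1)), "exactly one of"),
        (dict(family="triangular", min=3.0, mode=1.0, max=9.0), "min <= mode <= max"),
        (dict(family="uniform", low=2.0, high=1.0), "low <= high"),
        (dict(family="lognormal", mean=-1.0, sigma_log=0.5), "must be > 0"),
        (dict(family="empirical", samples=()), "requires samples"),
        (dict(family="point", value=1.0, lower_bound=2.0, upper_bound=1.0), "lower_bound > upper_bound"),
    ],
)
def test_invalid_specs_are_rejected(kwargs, message):
    with pytest.raises(ValueError, match=message):
        DistributionSpec(**kwargs)


def test_c90_key_is_canonicalized_to_sd():
    spec = DistributionSpec(family="normal", mean=12.6, c90=(12.3, 12.9))
    assert spec.c90 is None
    assert spec.sd == pytest.approx((12.9 - 12.3) / (2 * Z90))
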