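"""Sampleable descriptions of uncertain scalar parameters.

Every uncertain input to the burden pipeline — a participation proportion, an
illness probability, a unit cost — is declared as a :class:`DistributionSpec`:
a distribution family, its parameters, and optional truncation bounds.  Draws
outside the bounds are clipped (not resampled), so the number of underlying
random variates consumed per parameter is always exactly one per iteration,
which keeps a seeded run reproducible regardless of where truncation binds.

Quantities reported in the literature as a mean with a central-90% interval
(the 5th–95th percentile band) or a 95% confidence interval are converted to
normal distributions by :func:`spec_from_c90` / :func:`spec_from_ci95`, which
invert the corresponding normal quantile width.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats

__all__ = [
    "DistributionSpec",
    "sample",
    "analytic_mean",
    "spec_from_c90",
    "spec_from_ci95",
    "point",
]

Family = Literal[
    "point",
    "uniform",
    "normal",
    "truncated_normal",
    "triangular",
    "pert",
    "lognormal",
    "empirical",
]

#: z-score of the 95th percentile of the standard normal; a central-90%
#: interval of a normal spans 2 * Z90 standard deviations.
Z90 = float(stats.norm.ppf(0.95))
#: half-width of a 95% CI in standard deviations.
Z95 = float(stats.norm.ppf(0.975))


class DistributionSpec(BaseModel):
    """One uncertain parameter: family, family-specific parameters, bounds.

    Family parameter keys:

    ``point``
        ``value``
    ``uniform``
        ``low``, ``high``
    ``normal`` / ``truncated_normal``
        ``mean`` plus exactly one of ``sd``, ``c90`` (``[p5, p95]``) or
        ``ci95`` (``[lo, hi]``); interval forms are converted to an sd at
        validation time.
    ``triangular`` / ``pert``
        ``min``, ``mode``, ``max``
    ``lognormal``
        ``mean`` (arithmetic) and ``sigma_log`` (sd of log X)
    ``empirical``
        ``samples`` (resampled with replacement)

    ``lower_bound`` / ``upper_bound`` clip draws after sampling.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    family: Family
    value: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    c90: Optional[tuple[float, float]] = None
    ci95: Optional[tuple[float, float]] = None
    min: Optional[float] = None
    mode: Optional[float] = None
    max: Optional[float] = None
    sigma_log: Optional[float] = None
    samples: Optional[tuple[float, ...]] = None
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        f = self.family
        def need(*names: str) -> None:
            for n in names:
                if getattr(self, n) is None:
                    raise ValueError(f"invalid parameter: {f} family requires '{n}'")

        if f == "point":
            need("value")
        elif f == "uniform":
            need("low", "high")
            if self.low > self.high:
                raise ValueError("invalid parameter: uniform requires low <= high")
        elif f in ("normal", "truncated_normal"):
            need("mean")
            given = [k for k in ("sd", "c90", "ci95") if getattr(self, k) is not None]
            if len(given) != 1:
                raise ValueError(
                    "invalid parameter: normal requires exactly one of sd, c90, ci95"
                )
            # interval forms are canonicalized to an sd so that a serialized
            # spec re-validates (round-trip)
            if self.c90 is not None:
                lo, hi = self.c90
                if not lo <= self.mean <= hi:
                    raise ValueError("invalid C90: requires p5 <= mean <= p95")
                object.__setattr__(self, "sd", (hi - lo) / (2 * Z90))
                object.__setattr__(self, "c90", None)
            elif self.ci95 is not None:
                lo, hi = self.ci95
                if not lo <= self.mean <= hi:
                    raise ValueError("invalid parameter: ci95 must bracket the mean")
                object.__setattr__(self, "sd", (hi - lo) / (2 * Z95))
                object.__setattr__(self, "ci95", None)
            if self.sd is not None and self.sd <= 0:
                raise ValueError("invalid parameter: sd must be strictly positive")
        elif f in ("triangular", "pert"):
            need("min", "mode", "max")
            if not (self.min <= self.mode <= self.max):
                raise ValueError(f"invalid parameter: {f} requires min <= mode <= max")
        elif f == "lognormal":
            need("mean", "sigma_log")
            if self.mean <= 0:
                raise ValueError("invalid parameter: lognormal mean must be > 0")
            if self.sigma_log <= 0:
                raise ValueError("invalid parameter: sigma_log must be strictly positive")
        elif f == "empirical":
            need("samples")
            if len(self.samples) == 0:
                raise ValueError("invalid parameter: empirical requires samples")
        if self.lower_bound is not None and self.upper_bound is not None:
            if self.lower_bound > self.upper_bound:
                raise ValueError("invalid parameter: lower_bound > upper_bound")
        return self

    # -- convenience ------------------------------------------------------

    def clipped(self, lower: Optional[float], upper: Optional[float]) -> "DistributionSpec":
        """Return a copy with bounds tightened to [lower, upper]."""
        lo, hi = self.lower_bound, self.upper_bound
        if lower is not None:
            lo = lower if lo is None else max(lo, lower)
        if upper is not None:
            hi = upper if hi is None else min(hi, upper)
        return self.model_copy(update={"lower_bound": lo, "upper_bound": hi})


def point(value: float) -> DistributionSpec:
    """Degenerate distribution putting all mass on ``value``."""
    return DistributionSpec(family="point", value=float(value))


def _pert_beta_params(mn: float, mode: float, mx: float) -> tuple[float, float]:
    # standard (lambda = 4) PERT reparameterization as a scaled Beta
    span = mx - mn
    a = 1.0 + 4.0 * (mode - mn) / span
    b = 1.0 + 4.0 * (mx - mode) / span
    return a, b


def sample(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> float | np.ndarray:
    """Draw from ``spec``; draws outside the declared bounds are clipped.

    With ``size=None`` a scalar is returned, otherwise an ndarray of draws.
    """
    f = spec.family
    if f == "point":
        out = np.full(size or 1, spec.value, dtype=float)
    elif f == "uniform":
        if spec.low == spec.high:
            out = np.full(size or 1, spec.low, dtype=float)
        else:
            out = rng.uniform(spec.low, spec.high, size=size or 1)
    elif f in ("normal", "truncated_normal"):
        out = rng.normal(spec.mean, spec.sd, size=size or 1)
    elif f == "triangular":
        if spec.min == spec.max:
            out = np.full(size or 1, spec.min, dtype=float)
        else:
            out = rng.triangular(spec.min, spec.mode, spec.max, size=size or 1)
    elif f == "pert":
        if spec.min == spec.max:
            out = np.full(size or 1, spec.min, dtype=float)
        else:
            a, b = _pert_beta_params(spec.min, spec.mode, spec.max)
            out = spec.min + (spec.max - spec.min) * rng.beta(a, b, size=size or 1)
    elif f == "lognormal":
        mu = math.log(spec.mean) - 0.5 * spec.sigma_log**2
        out = rng.lognormal(mu, spec.sigma_log, size=size or 1)
    elif f == "empirical":
        out = rng.choice(np.asarray(spec.samples, dtype=float), size=size or 1)
    else:  # pragma: no cover - exhaustive over Family
        raise ValueError(f"unknown family {f!r}")

    lo = -np.inf if spec.lower_bound is None else spec.lower_bound
    hi = np.inf if spec.upper_bound is None else spec.upper_bound
    if spec.lower_bound is not None or spec.upper_bound is not None:
        np.clip(out, lo, hi, out=out)
    return float(out[0]) if size is None else out


def _frozen(spec: DistributionSpec):
    """scipy frozen distribution for the unclipped family, or None."""
    f = spec.family
    if f == "uniform":
        return stats.uniform(spec.low, spec.high - spec.low)
    if f in ("normal", "truncated_normal"):
        return stats.norm(spec.mean, spec.sd)
    if f == "triangular":
        span = spec.max - spec.min
        return stats.triang((spec.mode - spec.min) / span, loc=spec.min, scale=span)
    if f == "pert":
        a, b = _pert_beta_params(spec.min, spec.mode, spec.max)
        return stats.beta(a, b, loc=spec.min, scale=spec.max - spec.min)
    if f == "lognormal":
        mu = math.log(spec.mean) - 0.5 * spec.sigma_log**2
        return stats.lognorm(spec.sigma_log, scale=math.exp(mu))
    return None


def analytic_mean(spec: DistributionSpec) -> float:
    """Exact expectation of a draw, accounting for clipping at the bounds.

    For a clipped random variable Y = min(max(X, a), b),
    E[Y] = a F(a) + b (1 - F(b)) + E[X; a < X < b], evaluated in closed form
    for the normal family and by quadrature otherwise.
    """
    f = spec.family
    if f == "point":
        x = spec.value
        lo = -math.inf if spec.lower_bound is None else spec.lower_bound
        hi = math.inf if spec.upper_bound is None else spec.upper_bound
        return min(max(x, lo), hi)
    if f == "empirical":
        arr = np.asarray(spec.samples, dtype=float)
        lo = -np.inf if spec.lower_bound is None else spec.lower_bound
        hi = np.inf if spec.upper_bound is None else spec.upper_bound
        return float(np.mean(np.clip(arr, lo, hi)))

    a = -math.inf if spec.lower_bound is None else spec.lower_bound
    b = math.inf if spec.upper_bound is None else spec.upper_bound
    dist = _frozen(spec)
    lo_supp, hi_supp = dist.support()
    # bounds that sit outside the support never clip; use the closed form
    if a <= lo_supp and b >= hi_supp:
        if f == "uniform":
            return 0.5 * (spec.low + spec.high)
        if f in ("normal", "truncated_normal"):
            return spec.mean
        if f == "triangular":
            return (spec.min + spec.mode + spec.max) / 3.0
        if f == "pert":
            return (spec.min + 4.0 * spec.mode + spec.max) / 6.0
        if f == "lognormal":
            return spec.mean

    if f in ("normal", "truncated_normal"):
        # closed form for the clipped normal
        mu, sd = spec.mean, spec.sd
        alpha = (a - mu) / sd if math.isfinite(a) else -math.inf
        beta = (b - mu) / sd if math.isfinite(b) else math.inf
        Fa = stats.norm.cdf(alpha)
        Fb = stats.norm.cdf(beta)
        fa = stats.norm.pdf(alpha) if math.isfinite(alpha) else 0.0
        fb = stats.norm.pdf(beta) if math.isfinite(beta) else 0.0
        mass_a = a * Fa if math.isfinite(a) else 0.0
        mass_b = b * (1.0 - Fb) if math.isfinite(b) else 0.0
        return float(mass_a + mass_b + mu * (Fb - Fa) - sd * (fb - fa))
    interior = dist.expect(lb=a, ub=b)
    mass_a = a * dist.cdf(a) if math.isfinite(a) else 0.0
    mass_b = b * dist.sf(b) if math.isfinite(b) else 0.0
    return float(mass_a + mass_b + interior)


def spec_from_c90(
    mean: float,
    p5: float,
    p95: float,
    lower_bound: Optional[float] = None,
    upper_bound: Optional[float] = None,
) -> DistributionSpec:
    """Normal spec reproducing a reported mean with central-90% interval.

    The scale is (p95 - p5) / (2 * z_0.95); location is the reported mean.
    A zero-width interval collapses to a point mass.
    """
    if not (p5 <= mean <= p95):
        raise ValueError("invalid C90: requires p5 <= mean <= p95")
    if p5 == p95:
        return point(mean)
    return DistributionSpec(
        family="normal",
        mean=float(mean),
        sd=(p95 - p5) / (2 * Z90),
        lower_bound=lower_bound,
        upper_bound=upper_bound,
    )


def spec_from_ci95(
    mean: float,
    lo: float,
    hi: float,
    lower_bound: Optional[float] = None,
    upper_bound: Optional[float] = None,
) -> DistributionSpec:
    """Normal spec from a reported mean with 95% confidence interval."""
    if not (lo <= mean <= hi):
        raise ValueError("invalid parameter: ci95 must bracket the mean")
    if lo == hi:
        return point(mean)
    return DistributionSpec(
        family="normal",
        mean=float(mean),
        sd=(hi - lo) / (2 * Z95),
        lower_bound=lower_bound,
        upper_bound=upper_bound,
    )
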