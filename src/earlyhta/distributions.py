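"""Sampling distributions for probabilistic sensitivity analysis.

A :class:`DistributionSpec` names a parametric family and its parameters.
Conventions follow standard PSA practice: beta for probabilities and
utilities, gamma for costs, lognormal for hazard ratios, with uniform and
triangular as fallbacks. Method-of-moments constructors derive a spec from
a parameter's base value and (low, high) range, interpreting the range as
an approximate 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DistributionSpec", "spec_from_range"]

_FAMILIES = {"beta", "gamma", "lognormal", "uniform", "triangular"}


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric sampling distribution.

    Parameters by family:

    - ``beta``: (alpha, beta), both > 0; support (0, 1)
    - ``gamma``: (shape, scale), both > 0; support (0, inf)
    - ``lognormal``: (mu, sigma) of log(X), sigma > 0; support (0, inf)
    - ``uniform``: (low, high), low < high
    - ``triangular``: (low, mode, high), low <= mode <= high, low < high
    """

    family: str
    parameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {sorted(_FAMILIES)}"
            )
        p = tuple(float(x) for x in self.parameters)
        object.__setattr__(self, "parameters", p)
        if self.family == "beta":
            a, b = p
            if a <= 0 or b <= 0:
                raise ValueError(f"beta parameters must be positive, got {p}")
        elif self.family == "gamma":
            shape, scale = p
            if shape <= 0 or scale <= 0:
                raise ValueError(f"gamma parameters must be positive, got {p}")
        elif self.family == "lognormal":
            _, sigma = p
            if sigma <= 0:
                raise ValueError(f"lognormal sigma must be positive, got {p}")
        elif self.family == "uniform":
            low, high = p
            if not low < high:
                raise ValueError(f"uniform requires low < high, got {p}")
        elif self.family == "triangular":
            low, mode, high = p
            if not (low <= mode <= high and low < high):
                raise ValueError(f"invalid triangular parameters {p}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution using ``rng``."""
        p = self.parameters
        if self.family == "beta":
            return rng.beta(p[0], p[1], size=size)
        if self.family == "gamma":
            return rng.gamma(shape=p[0], scale=p[1], size=size)
        if self.family == "lognormal":
            return rng.lognormal(mean=p[0], sigma=p[1], size=size)
        if self.family == "uniform":
            return rng.uniform(p[0], p[1], size=size)
        return rng.triangular(p[0], p[1], p[2], size=size)

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        p = self.parameters
        if self.family == "beta":
            return p[0] / (p[0] + p[1])
        if self.family == "gamma":
            return p[0] * p[1]
        if self.family == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if self.family == "uniform":
            return 0.5 * (p[0] + p[1])
        return (p[0] + p[1] + p[2]) / 3.0

    @property
    def support(self) -> tuple[float, float]:
        p = self.parameters
        if self.family == "beta":
            return (0.0, 1.0)
        if self.family in ("gamma", "lognormal"):
            return (0.0, math.inf)
        if self.family == "uniform":
            return (p[0], p[1])
        return (p[0], p[2])


def spec_from_range(
    kind: str, base: float, low: float, high: float
) -> DistributionSpec:
    """Derive a default distribution from a base value and range.

    The (low, high) range is read as an approximate central 95% interval,
    so sd = (high - low) / 3.92. Family by parameter kind: beta for
    probabilities/utilities (method of moments, mean = base), gamma for
    costs (mean = base), lognormal for hazard ratios and rates
    (median = base), uniform otherwise. Degenerate ranges (high == low)
    fall back to a narrow uniform around the base.
    """
    sd = (high - low) / 3.92
    if sd <= 0:
        eps = max(abs(base) * 1e-9, 1e-12)
        return DistributionSpec("uniform", (base - eps, base + eps))
    if kind in ("probability", "utility"):
        m = min(max(base, 1e-9), 1 - 1e-9)
        # method of moments; cap variance below the Bernoulli bound
        var = min(sd**2, 0.99 * m * (1 - m))
        nu = m * (1 - m) / var - 1.0
        return DistributionSpec("beta", (m * nu, (1 - m) * nu))
    if kind == "cost" or kind == "count":
        shape = (base / sd) ** 2
        scale = sd**2 / base
        return DistributionSpec("gamma", (shape, scale))
    if kind in ("hazard-ratio", "rate"):
        sigma = (math.log(high) - math.log(low)) / 3.92
        return DistributionSpec("lognormal", (math.log(base), sigma))
    return DistributionSpec("uniform", (low, high))
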