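"""Economic outcomes: discounted costs, life-years, QALYs, ICERs, headroom.

Turns cohort traces into per-arm results, compares two strategy arms
(incremental costs and effects, ICERs, dominance), and implements the
headroom formula ``headroom = N + lambda * Q`` — the maximum justifiable
price of a technology given the savings N it generates at zero technology
cost and the monetised value of its health gain Q at willingness-to-pay
lambda — together with net monetary benefit.

Also home of :class:`ParameterSet`, the single source of truth for model
numbers: each named parameter carries a base value, a (low, high) range
for one-way analyses, an optional sampling distribution for probabilistic
analyses, and a source tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, spec_from_range
from .engine import (
    CohortTrace,
    CyclePlan,
    StateModel,
    ValidationError,
    discount_factor,
    run_cohort,
)

__all__ = [
    "ParameterValue",
    "ParameterSet",
    "ArmResult",
    "ComparisonResult",
    "HeadroomResult",
    "accumulate_outcomes",
    "evaluate_arm",
    "compare_arms",
    "headroom",
    "net_monetary_benefit",
]

PARAMETER_KINDS = ("probability", "utility", "cost", "hazard-ratio", "rate", "count")


@dataclass(frozen=True)
class ParameterValue:
    """A named model input with base value, range and distribution."""

    name: str
    kind: str
    base: float
    low: float
    high: float
    distribution: Optional[DistributionSpec] = None
    source_tag: str = "assumption"

    def __post_init__(self) -> None:
        if self.kind not in PARAMETER_KINDS:
            raise ValidationError(
                f"parameter {self.name!r}: unknown kind {self.kind!r}"
            )
        if not self.low <= self.base <= self.high:
            raise ValidationError(
                f"parameter {self.name!r}: base {self.base} outside "
                f"[{self.low}, {self.high}]"
            )
        lo, hi = self.kind_support
        if not (lo <= self.low and self.high <= hi):
            raise ValidationError(
                f"parameter {self.name!r} of kind {self.kind}: range "
                f"[{self.low}, {self.high}] outside support [{lo}, {hi}]"
            )

    @property
    def kind_support(self) -> tuple[float, float]:
        if self.kind in ("probability", "utility"):
            return (0.0, 1.0)
        if self.kind in ("cost", "rate", "count"):
            return (0.0, math.inf)
        return (1e-12, math.inf)  # hazard-ratio: strictly positive

    def default_distribution(self) -> DistributionSpec:
        """Kind-matched distribution derived from base and range."""
        return spec_from_range(self.kind, self.base, self.low, self.high)


class ParameterSet:
    """An ordered, name-indexed collection of :class:`ParameterValue`.

    Read/written as a delimited table with columns
    (name, kind, base, low, high, dist_family, dist_arg1, dist_arg2,
    dist_arg3, source_tag).
    """

    def __init__(self, values: Iterable[ParameterValue] = ()):
        self._values: dict[str, ParameterValue] = {}
        for v in values:
            if v.name in self._values:
                raise ValidationError(f"duplicate parameter name {v.name!r}")
            self._values[v.name] = v

    def __getitem__(self, name: str) -> ParameterValue:
        try:
            return self._values[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __iter__(self) -> Iterator[ParameterValue]:
        return iter(self._values.values())

    def __len__(self) -> int:
        return len(self._values)

    @property
    def names(self) -> list[str]:
        return list(self._values)

    def base_values(self) -> dict[str, float]:
        return {v.name: v.base for v in self}

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """A copy with base values replaced; ranges widen to contain them."""
        unknown = set(overrides) - set(self._values)
        if unknown:
            raise ValidationError(f"unknown parameter overrides: {sorted(unknown)}")
        out = []
        for v in self:
            if v.name in overrides:
                b = float(overrides[v.name])
                v = replace(
                    v, base=b, low=min(v.low, b), high=max(v.high, b)
                )
            out.append(v)
        return ParameterSet(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self:
            dist = v.distribution
            args = list(dist.parameters) if dist else []
            args += [np.nan] * (3 - len(args))
            rows.append(
                {
                    "name": v.name,
                    "kind": v.kind,
                    "base": v.base,
                    "low": v.low,
                    "high": v.high,
                    "dist_family": dist.family if dist else "",
                    "dist_arg1": args[0],
                    "dist_arg2": args[1],
                    "dist_arg3": args[2],
                    "source_tag": v.source_tag,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "name", "kind", "base", "low", "high", "dist_family",
                "dist_arg1", "dist_arg2", "dist_arg3", "source_tag",
            ],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        values = []
        for _, row in df.iterrows():
            fam = row.get("dist_family", "")
            dist = None
            if isinstance(fam, str) and fam:
                args = [
                    float(row[c])
                    for c in ("dist_arg1", "dist_arg2", "dist_arg3")
                    if c in row and pd.notna(row[c])
                ]
                dist = DistributionSpec(fam, tuple(args))
            values.append(
                ParameterValue(
                    name=str(row["name"]),
                    kind=str(row["kind"]),
                    base=float(row["base"]),
                    low=float(row["low"]),
                    high=float(row["high"]),
                    distribution=dist,
                    source_tag=str(row.get("source_tag", "assumption")),
                )
            )
        return cls(values)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, keep_default_na=True))


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one strategy arm."""

    total_cost: float
    life_years: float
    qalys: float


@dataclass(frozen=True)
class ComparisonResult:
    """Intervention vs comparator: incrementals, ICERs, dominance.

    ICER fields are ``None`` (undefined, not zero) when the corresponding
    incremental effect is exactly zero; the dominance label carries the
    interpretation: 'dominant' (cheaper, at least as effective),
    'dominated' (costlier, at most as effective), else 'trade-off'.
    """

    comparator: ArmResult
    intervention: ArmResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: Optional[float]
    icer_per_qaly: Optional[float]
    dominance_label: str


@dataclass(frozen=True)
class HeadroomResult:
    """Headroom = N + lambda * Q."""

    N: float
    lam: float
    Q: float
    headroom: float


def accumulate_outcomes(
    trace: CohortTrace,
    model: StateModel,
    plan: CyclePlan,
    upfront_cost: float = 0.0,
) -> ArmResult:
    """Accumulate discounted cost, life-years and QALYs over a trace.

    cost  = upfront + sum_k df_c(t_k) * sum_s occ[k, s] * cost_per_cycle[s]
    LY    = sum_k df_e(t_k) * sum_{s transient} occ[k, s] * cycle_length
    QALY  = as LY but weighted by state utilities

    where k runs over cycles 0..n_cycles-1, t_k = k * cycle_length, and
    occ[k] is the start-of-cycle occupancy, replaced by the trapezoid
    (row k + row k+1)/2 when the plan's half-cycle correction is on.
    """
    if trace.state_names != model.state_names:
        raise ValidationError(
            "trace state names do not match model state names: "
            f"{trace.state_names} vs {model.state_names}"
        )
    if trace.n_cycles != plan.n_cycles:
        raise ValidationError(
            f"trace has {trace.n_cycles} cycles but plan expects {plan.n_cycles}"
        )
    occ = trace.occupancy
    if plan.half_cycle_correction:
        occ_eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_eff = occ[:-1]
    cl = plan.cycle_length_years
    times = np.arange(plan.n_cycles) * cl
    df_c = (1.0 + plan.discount_rate_costs) ** (-times)
    df_e = (1.0 + plan.discount_rate_effects) ** (-times)

    costs = np.array([s.cost_per_cycle for s in model.states])
    utils = np.array([s.utility for s in model.states])
    alive = (~model.absorbing_mask).astype(float)

    total_cost = upfront_cost + float(df_c @ (occ_eff @ costs))
    life_years = float(df_e @ (occ_eff @ alive)) * cl
    qalys = float(df_e @ (occ_eff @ (utils * alive))) * cl
    return ArmResult(total_cost=total_cost, life_years=life_years, qalys=qalys)


def evaluate_arm(
    model: StateModel,
    entry,
    plan: CyclePlan,
    upfront_cost: float = 0.0,
) -> ArmResult:
    """Convenience: run the cohort and accumulate outcomes in one call."""
    trace = run_cohort(model, entry, plan)
    return accumulate_outcomes(trace, model, plan, upfront_cost=upfront_cost)


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if (delta_cost < 0 and delta_qaly >= 0) or (delta_cost <= 0 and delta_qaly > 0):
        return "dominant"
    if (delta_cost > 0 and delta_qaly <= 0) or (delta_cost >= 0 and delta_qaly < 0):
        return "dominated"
    return "trade-off"


def compare_arms(comparator: ArmResult, intervention: ArmResult) -> ComparisonResult:
    """Incremental outcomes of intervention minus comparator."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_ly = intervention.life_years - comparator.life_years
    d_qaly = intervention.qalys - comparator.qalys
    icer_ly = d_cost / d_ly if d_ly != 0 else None
    icer_qaly = d_cost / d_qaly if d_qaly != 0 else None
    return ComparisonResult(
        comparator=comparator,
        intervention=intervention,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_qaly,
        dominance_label=_dominance(d_cost, d_qaly),
    )


def headroom(N: float, lam: float, Q: float) -> HeadroomResult:
    """Maximum justifiable technology price: N + lambda * Q.

    N: savings with the technology cost set to zero; lam: willingness to
    pay per unit of health effect; Q: health effects gained.
    """
    if lam < 0:
        raise ValidationError(f"willingness-to-pay must be non-negative, got {lam}")
    return HeadroomResult(N=N, lam=lam, Q=Q, headroom=N + lam * Q)


def net_monetary_benefit(delta_cost: float, delta_qaly: float, lam: float) -> float:
    """NMB = lambda * delta_QALY - delta_cost at willingness-to-pay lambda."""
    if lam < 0:
        raise ValidationError(f"willingness-to-pay must be non-negative, got {lam}")
    return lam * delta_qaly - delta_cost
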