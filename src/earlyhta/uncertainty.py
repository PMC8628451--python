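"""Uncertainty toolkit: one-way, scenario, probabilistic and threshold analyses.

All analyses are driven by a *model builder*: a callable mapping a dict of
parameter values (name -> float) to a :class:`ComparisonResult`. The
toolkit never inspects the model; it only re-evaluates the builder at
perturbed parameter vectors, which keeps it generic across case models.

- one-way (tornado) analysis: each parameter swept to its low/high bound
  with all others at base;
- scenario analysis: a named override map applied simultaneously;
- probabilistic sensitivity analysis (PSA): joint Monte-Carlo draws from
  each parameter's distribution, evaluated through the full model;
- cost-effectiveness acceptability curve (CEAC): fraction of PSA draws
  with strictly positive net monetary benefit across a willingness-to-pay
  grid (ties at exactly zero count as not cost-effective);
- threshold search: bisection for the parameter value at which a boolean
  outcome criterion flips (e.g. a price below which the technology is
  cost-saving);
- parameter sweep: full re-evaluation over a grid (e.g. prevalence).

Parameters are drawn independently; correlations between parameters are
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, spec_from_range  # noqa: F401  (re-export)
from .engine import ValidationError
from .health_econ import ComparisonResult, ParameterSet, net_monetary_benefit

__all__ = [
    "DistributionSpec",
    "ModelBuilder",
    "PSASampleSet",
    "CEACCurve",
    "TornadoEntry",
    "ThresholdResult",
    "owsa",
    "scenario",
    "psa",
    "ceac",
    "threshold_search",
    "parameter_sweep",
    "plot_ce_plane",
    "plot_ceac",
    "plot_tornado",
]

ModelBuilder = Callable[[Mapping[str, float]], ComparisonResult]

#: default willingness-to-pay grid for CEACs (EUR/QALY)
DEFAULT_LAMBDA_GRID = np.arange(0, 200_001, 1_000)


@dataclass(frozen=True)
class TornadoEntry:
    """One-way impact of a single parameter on a scalar outcome."""

    name: str
    outcome_low: float
    outcome_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


@dataclass
class PSASampleSet:
    """Joint Monte-Carlo draws with their incremental outcomes.

    ``parameters`` holds the sampled parameter vectors (one row per
    draw); ``delta_cost``/``delta_qaly``/``delta_ly`` the evaluated
    incremental outcomes. Regenerating with the same seed reproduces the
    draws bit-identically.
    """

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    parameters: pd.DataFrame
    seed: int
    n: int

    def __post_init__(self) -> None:
        if not (
            len(self.delta_cost) == len(self.delta_qaly) == self.n
        ):
            raise ValidationError("PSA sample arrays must have length n")

    def to_frame(self) -> pd.DataFrame:
        out = self.parameters.copy()
        out.insert(0, "delta_ly", self.delta_ly)
        out.insert(0, "delta_qaly", self.delta_qaly)
        out.insert(0, "delta_cost", self.delta_cost)
        return out


@dataclass(frozen=True)
class CEACCurve:
    """Probability of cost-effectiveness across willingness-to-pay values."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "probability": self.probabilities}
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold search; ``value`` is None when no flip exists."""

    parameter: str
    found: bool
    value: Optional[float]
    lo: float
    hi: float
    message: str = ""


def owsa(
    model_builder: ModelBuilder,
    params: ParameterSet,
    outcome_selector: Callable[[ComparisonResult], float],
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over every parameter.

    Each parameter is set to its low and high bound in turn with all
    others held at base, the full model re-evaluated, and the selected
    outcome recorded. Entries are returned sorted by bar width
    (descending), ready for a tornado diagram.
    """
    base = params.base_values()
    entries = []
    for p in params:
        outcomes = {}
        for bound_name, bound in (("low", p.low), ("high", p.high)):
            values = dict(base)
            values[p.name] = bound
            try:
                outcomes[bound_name] = float(outcome_selector(model_builder(values)))
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise ValidationError(
                    f"model evaluation failed for parameter {p.name!r} at "
                    f"{bound_name} bound {bound}: {exc}"
                ) from exc
        entries.append(
            TornadoEntry(
                name=p.name,
                outcome_low=outcomes["low"],
                outcome_high=outcomes["high"],
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def scenario(
    model_builder: ModelBuilder,
    params: ParameterSet,
    overrides: Mapping[str, float],
) -> ComparisonResult:
    """Evaluate the model once with named overrides applied simultaneously.

    The base :class:`ParameterSet` is left untouched.
    """
    unknown = set(overrides) - set(params.names)
    if unknown:
        raise ValidationError(f"unknown scenario overrides: {sorted(unknown)}")
    values = params.base_values()
    values.update({k: float(v) for k, v in overrides.items()})
    return model_builder(values)


def psa(
    model_builder: ModelBuilder,
    params: ParameterSet,
    n: int = 1000,
    seed: int = 0,
    on_missing_distribution: str = "hold",
) -> PSASampleSet:
    """Probabilistic sensitivity analysis: n joint draws through the model.

    Each parameter with a :class:`DistributionSpec` is sampled n times
    (independently across parameters); parameters without one are held at
    base when ``on_missing_distribution='hold'`` or rejected when
    ``'error'``. Draws outside the parameter's kind support are clipped
    into it. Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValidationError(f"PSA draw count must be >= 1, got {n}")
    if on_missing_distribution not in ("hold", "error"):
        raise ValidationError(
            "on_missing_distribution must be 'hold' or 'error'"
        )
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for p in params:  # fixed iteration order => deterministic stream
        if p.distribution is None:
            if on_missing_distribution == "error":
                raise ValidationError(
                    f"parameter {p.name!r} has no distribution for PSA"
                )
            columns[p.name] = np.full(n, p.base)
            continue
        draws = np.asarray(p.distribution.sample(rng, size=n), dtype=float)
        lo, hi = p.kind_support
        columns[p.name] = np.clip(draws, lo, min(hi, np.inf))
    table = pd.DataFrame(columns)

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    d_ly = np.empty(n)
    for i in range(n):
        res = model_builder({k: float(v) for k, v in table.iloc[i].items()})
        d_cost[i] = res.delta_cost
        d_qaly[i] = res.delta_qaly
        d_ly[i] = res.delta_ly
    return PSASampleSet(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        parameters=table,
        seed=seed,
        n=n,
    )


def ceac(samples: PSASampleSet, lambdas: Sequence[float] | None = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve from a PSA sample set.

    At each willingness-to-pay lambda, the probability is the fraction of
    draws with strictly positive net monetary benefit
    ``lambda * delta_qaly - delta_cost``.
    """
    if samples.n == 0:
        raise ValidationError("empty PSA sample set")
    grid = DEFAULT_LAMBDA_GRID if lambdas is None else np.asarray(lambdas, float)
    if grid.size == 0:
        raise ValidationError("empty willingness-to-pay grid")
    nmb = grid[:, None] * samples.delta_qaly[None, :] - samples.delta_cost[None, :]
    probs = (nmb > 0).mean(axis=1)
    return CEACCurve(lambdas=grid, probabilities=probs)


def threshold_search(
    model_builder: ModelBuilder,
    params: ParameterSet,
    target_param: str,
    criterion: Callable[[ComparisonResult], bool],
    lo: float | None = None,
    hi: float | None = None,
    tol: float = 0.01,
    check_grid: int = 0,
) -> ThresholdResult:
    """Bisection for the parameter value where ``criterion`` flips.

    The criterion is assumed monotone in the target parameter over
    [lo, hi] (defaults: the parameter's low/high range); optionally
    verified empirically on ``check_grid`` interior points (at most one
    truth-value change along the grid). When the criterion has the same
    truth value at both bounds a no-threshold result is returned rather
    than raising.
    """
    p = params[target_param]
    lo = p.low if lo is None else float(lo)
    hi = p.high if hi is None else float(hi)
    if not lo < hi:
        raise ValidationError(f"invalid search bounds [{lo}, {hi}]")

    base = params.base_values()

    def crit_at(x: float) -> bool:
        values = dict(base)
        values[target_param] = x
        return bool(criterion(model_builder(values)))

    c_lo, c_hi = crit_at(lo), crit_at(hi)
    if check_grid > 0:
        xs = np.linspace(lo, hi, check_grid + 2)
        flags = [crit_at(x) for x in xs]
        flips = sum(a != b for a, b in zip(flags, flags[1:]))
        if flips > 1:
            raise ValidationError(
                f"criterion is not monotone in {target_param!r} over "
                f"[{lo}, {hi}] ({flips} sign changes on the check grid)"
            )
    if c_lo == c_hi:
        return ThresholdResult(
            parameter=target_param,
            found=False,
            value=None,
            lo=lo,
            hi=hi,
            message=(
                f"criterion is {c_lo} across the whole range "
                f"[{lo}, {hi}]; no threshold in range"
            ),
        )
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if crit_at(mid) == c_lo:
            a = mid
        else:
            b = mid
    return ThresholdResult(
        parameter=target_param,
        found=True,
        value=0.5 * (a + b),
        lo=lo,
        hi=hi,
    )


def parameter_sweep(
    model_builder: ModelBuilder,
    params: ParameterSet,
    sweep_param: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Re-evaluate the full model over a grid of one parameter.

    All other parameters stay at base. Returns one row per grid point
    with the incremental outcomes and ICERs.
    """
    p = params[sweep_param]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty sweep grid")
    lo, hi = p.kind_support
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValidationError(
            f"sweep grid for {sweep_param!r} leaves the kind support "
            f"[{lo}, {hi}]"
        )
    base = params.base_values()
    rows = []
    for x in grid:
        values = dict(base)
        values[sweep_param] = float(x)
        res = model_builder(values)
        rows.append(
            {
                sweep_param: float(x),
                "delta_cost": res.delta_cost,
                "delta_ly": res.delta_ly,
                "delta_qaly": res.delta_qaly,
                "icer_per_qaly": res.icer_per_qaly,
                "dominance": res.dominance_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting (optional; all figures are written headlessly via Agg)


def _axes(path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    return plt, fig, ax


def plot_ce_plane(samples: PSASampleSet, path, lam: float | None = None) -> None:
    """Scatter of incremental QALYs vs incremental costs per PSA draw."""
    plt, fig, ax = _axes(path)
    ax.scatter(samples.delta_qaly, samples.delta_cost, s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if lam is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, lam * xs, color="firebrick", lw=0.8, label=f"λ = {lam:g}")
        ax.legend()
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path) -> None:
    plt, fig, ax = _axes(path)
    ax.plot(curve.lambdas, curve.probabilities)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("willingness to pay per QALY")
    ax.set_ylabel("probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: Sequence[TornadoEntry], path, base_outcome: float = 0.0) -> None:
    plt, fig, ax = _axes(path)
    entries = list(entries)
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo, hi = sorted((e.outcome_low, e.outcome_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="steelblue")
    ax.axvline(base_outcome, color="black", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.name for e in entries], fontsize=8)
    ax.set_xlabel("outcome")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
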