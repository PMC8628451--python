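"""Cohort-level simulation engine.

The engine knows nothing about economics beyond per-state payoffs: it
rolls decision trees back to an entry distribution plus an expected
upfront cost, and it propagates a cohort through a discrete-time Markov
state-transition model. Health states carry a per-cycle cost and a
utility weight; a transition model is a square row-stochastic matrix
(optionally a sequence of matrices for time-dependent transitions, e.g.
per-cycle probabilities digitised from a time-to-event curve).

Cycle accounting convention: a trace has ``n_cycles + 1`` rows, row 0
being the entry distribution; payoffs for cycle ``k`` (k = 0..n_cycles-1)
accrue on the occupancy at the start of the cycle, or on the trapezoid of
rows k and k+1 when the half-cycle correction is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "HealthState",
    "StateModel",
    "DecisionNode",
    "Branch",
    "CyclePlan",
    "CohortTrace",
    "ValidationError",
    "rollback_tree",
    "run_cohort",
    "hr_adjust_probability",
    "discount_factor",
]

#: row sums of a transition matrix must match 1 to this tolerance
ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """A model structure or input violated its invariants."""


@dataclass(frozen=True)
class HealthState:
    """A labelled health state with per-cycle payoffs.

    ``utility`` is a quality-of-life weight in [0, 1] per year-equivalent;
    ``cost_per_cycle`` is in currency units per model cycle. Absorbing
    states default to utility 0 and cost 0 unless explicitly overridden.
    """

    name: str
    is_absorbing: bool = False
    cost_per_cycle: float = 0.0
    utility: float | None = None

    def __post_init__(self) -> None:
        if self.utility is None:
            object.__setattr__(self, "utility", 0.0 if self.is_absorbing else 1.0)
        if not 0.0 <= self.utility <= 1.0:
            raise ValidationError(
                f"state {self.name!r}: utility {self.utility} outside [0, 1]"
            )
        if self.cost_per_cycle < 0:
            raise ValidationError(
                f"state {self.name!r}: negative cost_per_cycle {self.cost_per_cycle}"
            )


def _validate_matrix(
    mat: np.ndarray, states: Sequence[HealthState], label: str
) -> np.ndarray:
    n = len(states)
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n, n):
        raise ValidationError(
            f"{label}: transition matrix shape {mat.shape} does not match "
            f"{n} states"
        )
    if np.any(mat < -ROW_SUM_TOL) or np.any(mat > 1 + ROW_SUM_TOL):
        raise ValidationError(f"{label}: transition probabilities outside [0, 1]")
    mat = np.clip(mat, 0.0, 1.0)
    rowsums = mat.sum(axis=1)
    bad = np.abs(rowsums - 1.0) >= ROW_SUM_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"{label}: row {i} ({states[i].name!r}) sums to {rowsums[i]:.12g}, "
            f"not 1 within {ROW_SUM_TOL}"
        )
    # renormalise sub-tolerance float noise so downstream sums are exact
    mat = mat / rowsums[:, None]
    for i, s in enumerate(states):
        if s.is_absorbing:
            row = np.zeros(n)
            row[i] = 1.0
            if not np.allclose(mat[i], row, atol=ROW_SUM_TOL):
                raise ValidationError(
                    f"{label}: absorbing state {s.name!r} row is not an "
                    "identity row"
                )
            mat[i] = row
    return mat


@dataclass
class StateModel:
    """A Markov cohort state-transition model.

    ``transitions`` is a single (n, n) row-stochastic array or a sequence
    of them for time-dependent transitions; when the simulated horizon
    exceeds the sequence length the final matrix is reused for the
    remaining cycles. ``cycle_length_years`` converts cycles to time.
    """

    states: list[HealthState]
    transitions: Union[np.ndarray, Sequence[np.ndarray]]
    cycle_length_years: float = 1.0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("StateModel requires at least one state")
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be positive")
        if not any(s.is_absorbing for s in self.states):
            raise ValidationError("StateModel requires at least one absorbing state")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate state names in {names}")
        if isinstance(self.transitions, np.ndarray) and self.transitions.ndim == 2:
            self.transitions = _validate_matrix(self.transitions, self.states, "model")
            self._time_dependent = False
        else:
            mats = [
                _validate_matrix(m, self.states, f"model[cycle {t}]")
                for t, m in enumerate(self.transitions)
            ]
            if not mats:
                raise ValidationError("empty transition-matrix sequence")
            self.transitions = mats
            self._time_dependent = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def absorbing_mask(self) -> np.ndarray:
        return np.array([s.is_absorbing for s in self.states])

    def matrix_at(self, cycle: int) -> np.ndarray:
        """Transition matrix governing cycle ``cycle`` (0-based)."""
        if not self._time_dependent:
            return self.transitions
        seq = self.transitions
        return seq[min(cycle, len(seq) - 1)]

    def entry_distribution(
        self, entry: Union[Mapping[str, float], Sequence[float]]
    ) -> np.ndarray:
        """Coerce a mapping or sequence to a validated entry vector."""
        if isinstance(entry, Mapping):
            unknown = set(entry) - set(self.state_names)
            if unknown:
                raise ValidationError(f"unknown states in entry distribution: {unknown}")
            vec = np.array([float(entry.get(n, 0.0)) for n in self.state_names])
        else:
            vec = np.asarray(entry, dtype=float)
            if vec.shape != (self.n_states,):
                raise ValidationError(
                    f"entry distribution length {vec.shape} does not match "
                    f"{self.n_states} states"
                )
        if np.any(vec < 0) or abs(vec.sum() - 1.0) >= ROW_SUM_TOL:
            raise ValidationError(
                f"entry distribution must be non-negative and sum to 1, got {vec}"
            )
        return vec / vec.sum()


@dataclass
class CyclePlan:
    """Time horizon, cycle length, discounting and half-cycle correction.

    Discount rates are annual fractions applied as 1/(1+r)^t with t in
    years; costs and effects may be discounted at different rates.
    """

    horizon_years: float
    cycle_length_years: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years <= 0 or self.cycle_length_years <= 0:
            raise ValidationError("horizon and cycle length must be positive")
        ratio = self.horizon_years / self.cycle_length_years
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"horizon {self.horizon_years}y is not an integer multiple of "
                f"cycle length {self.cycle_length_years}y"
            )
        for r in (self.discount_rate_costs, self.discount_rate_effects):
            if not 0.0 <= r < 1.0:
                raise ValidationError(f"discount rate {r} outside [0, 1)")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


@dataclass
class CohortTrace:
    """State occupancy per cycle; row 0 is the entry distribution."""

    occupancy: np.ndarray
    state_names: list[str]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


Branch = tuple  # (probability, payoff_cost, child)


@dataclass
class DecisionNode:
    """A chance/decision node whose branches carry probability and cost.

    Each branch is ``(probability, payoff_cost, child)`` where ``child``
    is either another :class:`DecisionNode` or a terminal entry
    distribution (mapping of state name to fraction, or a vector).
    """

    label: str
    branches: list[Branch] = field(default_factory=list)


def rollback_tree(
    root: DecisionNode, state_names: Sequence[str]
) -> tuple[np.ndarray, float]:
    """Roll a decision tree back to (entry distribution, expected cost).

    The entry distribution is the probability-weighted mixture of the
    terminal distributions; the expected cost is the probability-weighted
    sum of payoff costs along every root-to-terminal path.
    """
    names = list(state_names)
    n = len(names)

    def _terminal_vec(term) -> np.ndarray:
        if isinstance(term, Mapping):
            unknown = set(term) - set(names)
            if unknown:
                raise ValidationError(f"terminal references unknown states {unknown}")
            vec = np.array([float(term.get(s, 0.0)) for s in names])
        else:
            vec = np.asarray(term, dtype=float)
            if vec.shape != (n,):
                raise ValidationError(
                    f"terminal distribution length {vec.shape} != {n} states"
                )
        if np.any(vec < 0) or abs(vec.sum() - 1.0) >= ROW_SUM_TOL:
            raise ValidationError(
                f"terminal distribution must sum to 1, got {vec}"
            )
        return vec / vec.sum()

    def _roll(node: DecisionNode) -> tuple[np.ndarray, float]:
        if not node.branches:
            raise ValidationError(f"node {node.label!r} has no branches")
        probs = np.array([float(b[0]) for b in node.branches])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) >= ROW_SUM_TOL:
            raise ValidationError(
                f"branch probabilities at node {node.label!r} sum to "
                f"{probs.sum():.12g}, not 1"
            )
        dist = np.zeros(n)
        cost = 0.0
        for (p, branch_cost, child), pnorm in zip(node.branches, probs / probs.sum()):
            if isinstance(child, DecisionNode):
                cdist, ccost = _roll(child)
            else:
                cdist, ccost = _terminal_vec(child), 0.0
            dist += pnorm * cdist
            cost += pnorm * (float(branch_cost) + ccost)
        return dist, cost

    return _roll(root)


def run_cohort(
    model: StateModel,
    entry: Union[Mapping[str, float], Sequence[float], np.ndarray],
    plan: CyclePlan,
) -> CohortTrace:
    """Propagate a cohort through ``model`` for the planned horizon.

    Returns a trace with ``plan.n_cycles + 1`` rows: row t is the entry
    distribution left-multiplied by the first t transition matrices.
    """
    if abs(model.cycle_length_years - plan.cycle_length_years) > 1e-12:
        raise ValidationError(
            f"model cycle length {model.cycle_length_years}y does not match "
            f"plan cycle length {plan.cycle_length_years}y"
        )
    vec = model.entry_distribution(entry)
    n_cycles = plan.n_cycles
    occ = np.empty((n_cycles + 1, model.n_states))
    occ[0] = vec
    for t in range(n_cycles):
        vec = vec @ model.matrix_at(t)
        occ[t + 1] = vec
    return CohortTrace(occupancy=occ, state_names=model.state_names)


def hr_adjust_probability(p: float, hr: float) -> float:
    """Apply a hazard ratio to a per-cycle transition probability.

    Converts the probability to a rate, scales the rate by ``hr`` and
    converts back: ``1 - (1 - p) ** hr``. This is the standard
    constant-rate-within-cycle application of a hazard ratio.
    """
    if hr <= 0:
        raise ValidationError(f"hazard ratio must be positive, got {hr}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1]")
    if hr == 1.0:
        return p  # exact fixed point; 1-(1-p)**1.0 would round away from p
    if p == 1.0:
        raise ValidationError(
            "cannot apply a hazard ratio to p = 1: the underlying rate is "
            "undefined"
        )
    return 1.0 - (1.0 - p) ** hr


def discount_factor(t: float, rate: float) -> float:
    """Discount factor 1/(1 + rate)^t for time ``t`` in years."""
    if t < 0:
        raise ValidationError(f"time {t} must be non-negative")
    if not 0.0 <= rate < 1.0:
        raise ValidationError(f"discount rate {rate} outside [0, 1)")
    return (1.0 + rate) ** (-t)
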