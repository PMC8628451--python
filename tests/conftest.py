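"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from earlyhta.engine import CyclePlan, HealthState, StateModel
from earlyhta.health_econ import ArmResult, ParameterSet, ParameterValue, compare_arms


def random_state_model(rng: np.random.Generator, n_states: int) -> StateModel:
    """A random valid model: last state absorbing, rows Dirichlet-ish."""
    mat = rng.random((n_states, n_states))
    mat = mat / mat.sum(axis=1, keepdims=True)
    mat[-1] = 0.0
    mat[-1, -1] = 1.0
    states = [
        HealthState(
            name=f"s{i}",
            cost_per_cycle=float(rng.uniform(0, 1000)),
            utility=float(rng.uniform(0, 1)),
        )
        for i in range(n_states - 1)
    ]
    states.append(HealthState(name="dead", is_absorbing=True))
    return StateModel(states=states, transitions=mat, cycle_length_years=1.0)


def naive_trace_oracle(matrices, entry: np.ndarray, n_cycles: int) -> np.ndarray:
    """Step-by-step occupancy, written independently of the engine.

    ``matrices`` is a callable cycle -> matrix; the multiplication is an
    explicit double loop over states rather than a matmul.
    """
    n = len(entry)
    occ = [np.array(entry, dtype=float)]
    for t in range(n_cycles):
        mat = matrices(t)
        nxt = np.zeros(n)
        for j in range(n):
            for i in range(n):
                nxt[j] += occ[-1][i] * mat[i, j]
        occ.append(nxt)
    return np.array(occ)


def spreadsheet_outcomes_oracle(
    occ: np.ndarray,
    costs: np.ndarray,
    utilities: np.ndarray,
    absorbing: np.ndarray,
    plan: CyclePlan,
    upfront: float,
) -> tuple[float, float, float]:
    """Cycle-by-cycle accumulation, spreadsheet style (explicit loops)."""
    total_cost = upfront
    ly = 0.0
    qaly = 0.0
    cl = plan.cycle_length_years
    for k in range(plan.n_cycles):
        if plan.half_cycle_correction:
            row = 0.5 * (occ[k] + occ[k + 1])
        else:
            row = occ[k]
        t = k * cl
        dfc = 1.0 / (1.0 + plan.discount_rate_costs) ** t
        dfe = 1.0 / (1.0 + plan.discount_rate_effects) ** t
        for s in range(len(row)):
            total_cost += dfc * row[s] * costs[s]
            if not absorbing[s]:
                ly += dfe * row[s] * cl
                qaly += dfe * row[s] * utilities[s] * cl
    return total_cost, ly, qaly


def make_linear_builder(cost_coeffs: dict, qaly_coeffs: dict, intercept_cost=0.0,
                        intercept_qaly=0.0):
    """A toy comparison whose increments are affine in the parameters."""

    def builder(values):
        d_cost = intercept_cost + sum(
            c * values[name] for name, c in cost_coeffs.items()
        )
        d_qaly = intercept_qaly + sum(
            c * values[name] for name, c in qaly_coeffs.items()
        )
        comparator = ArmResult(total_cost=50_000.0, life_years=10.0, qalys=8.0)
        intervention = ArmResult(
            total_cost=50_000.0 + d_cost,
            life_years=10.0,
            qalys=8.0 + d_qaly,
        )
        return compare_arms(comparator, intervention)

    return builder


@pytest.fixture
def two_state_model() -> StateModel:
    mat = np.array([[0.5, 0.5], [0.0, 1.0]])
    return StateModel(
        states=[
            HealthState(name="alive", cost_per_cycle=100.0, utility=0.5),
            HealthState(name="dead", is_absorbing=True),
        ],
        transitions=mat,
        cycle_length_years=1.0,
    )


@pytest.fixture
def toy_params() -> ParameterSet:
    return ParameterSet(
        [
            ParameterValue("price", "cost", 15.0, 10.0, 20.0),
            ParameterValue("n_patients", "count", 100.0, 100.0, 100.0),
            ParameterValue("savings", "cost", 500.0, 0.0, 1000.0),
            ParameterValue("effect", "utility", 0.1, 0.0, 0.2),
        ]
    )
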