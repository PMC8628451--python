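"""Config-driven case models: CLL stratification and ICU CRBSI detection.

Two early economic evaluations of clinical analytics ship with the
package as config bundles (model structure YAML + parameter table CSV +
scenario YAML):

- ``cll``: analytics to stratify newly diagnosed watch-and-wait chronic
  lymphocytic leukaemia patients, treating the flagged high-risk fraction
  early with ibrutinib. The early-treatment effect enters as a hazard
  ratio on the per-cycle probability of needing the next treatment line.
- ``crbsi``: analytics for early detection of catheter-related
  bloodstream infections in the ICU. A decision tree (infection yes/no,
  early vs late detection consequences: extra length of stay as an
  upfront cost, attributable ICU mortality as a shift of the entry
  distribution) feeds a shared four-state Markov model; the technology is
  priced per bed and spread over the bed's annual patient throughput.

Both state sets and all parameter values not printed in the underlying
main-text tables are illustrative reconstructions (source_tag =
assumption); absolute totals are not calibrated to any published model.

The module also provides the generic config layer: transition and payoff
values in ``model.yaml`` are *expressions* resolved against a parameter
vector — a number, a parameter name, or a tagged combinator:
``{hr_adjust: [p, hr]}``, ``{sum: [...]}``, ``{product: [...]}``,
``{ratio: [num, den]}``, ``{complement: x}``,
``{mix: [[weight, value], ...]}``, ``{lerp: [a, b, w]}`` (= a + w(b-a),
which collapses exactly to ``a`` when the endpoints coincide — used for
intervention rows so null interventions give bit-exact zero increments).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .engine import (
    CyclePlan,
    DecisionNode,
    HealthState,
    StateModel,
    ValidationError,
    hr_adjust_probability,
    rollback_tree,
)
from .health_econ import (
    ComparisonResult,
    ParameterSet,
    compare_arms,
    evaluate_arm,
)

__all__ = [
    "CaseModel",
    "available_cases",
    "load_case",
    "build_cll_model",
    "build_crbsi_model",
    "resolve_expression",
    "state_model_from_config",
    "decision_tree_from_config",
]


def resolve_expression(expr, values: Mapping[str, float]) -> float:
    """Resolve a config expression against a parameter vector."""
    if isinstance(expr, (int, float)):
        return float(expr)
    if isinstance(expr, str):
        if expr not in values:
            raise ValidationError(f"unresolved parameter reference {expr!r}")
        return float(values[expr])
    if isinstance(expr, Mapping) and len(expr) == 1:
        (op, arg), = expr.items()
        if op == "hr_adjust":
            p, hr = (resolve_expression(a, values) for a in arg)
            return hr_adjust_probability(p, hr)
        if op == "sum":
            return sum(resolve_expression(a, values) for a in arg)
        if op == "product":
            out = 1.0
            for a in arg:
                out *= resolve_expression(a, values)
            return out
        if op == "ratio":
            num, den = (resolve_expression(a, values) for a in arg)
            if den == 0:
                raise ValidationError("ratio expression with zero denominator")
            return num / den
        if op == "complement":
            return 1.0 - resolve_expression(arg, values)
        if op == "lerp":
            # a + w * (b - a): exact null when a == b, unlike a 2-term mix
            a, b, w = (resolve_expression(x, values) for x in arg)
            return a + w * (b - a)
        if op == "mix":
            return sum(
                resolve_expression(w, values) * resolve_expression(v, values)
                for w, v in arg
            )
    raise ValidationError(f"cannot resolve config expression {expr!r}")


def state_model_from_config(
    states_cfg: list[dict],
    arm_cfg: Mapping,
    cycle_length_years: float,
    values: Mapping[str, float],
) -> StateModel:
    """Build a StateModel from a state list and an arm's bindings.

    Transitions come as an edge list; an unspecified diagonal entry
    implies the residual "stay" probability 1 - sum(row off-diagonals).
    Per-arm ``state_costs`` / ``state_utilities`` override the defaults
    (0 cost; utility 1 transient, 0 absorbing).
    """
    names = [s["name"] for s in states_cfg]
    index = {n: i for i, n in enumerate(names)}
    costs = {
        k: resolve_expression(v, values)
        for k, v in (arm_cfg.get("state_costs") or {}).items()
    }
    utils = {
        k: resolve_expression(v, values)
        for k, v in (arm_cfg.get("state_utilities") or {}).items()
    }
    states = []
    for s in states_cfg:
        absorbing = bool(s.get("absorbing", False))
        states.append(
            HealthState(
                name=s["name"],
                is_absorbing=absorbing,
                cost_per_cycle=costs.get(s["name"], 0.0),
                utility=utils.get(s["name"], None),
            )
        )
    n = len(names)
    mat = np.zeros((n, n))
    diag_set = np.zeros(n, dtype=bool)
    for edge in arm_cfg.get("transitions", []):
        i, j = index[edge["from"]], index[edge["to"]]
        mat[i, j] = resolve_expression(edge["value"], values)
        if i == j:
            diag_set[i] = True
    for i, s in enumerate(states):
        if s.is_absorbing:
            mat[i] = 0.0
            mat[i, i] = 1.0
        elif not diag_set[i]:
            off = mat[i].sum() - mat[i, i]
            if off > 1 + 1e-9:
                raise ValidationError(
                    f"row {names[i]!r}: off-diagonal transitions sum to {off:.6g} > 1"
                )
            mat[i, i] = max(1.0 - off, 0.0)
    return StateModel(states=states, transitions=mat, cycle_length_years=cycle_length_years)


def decision_tree_from_config(tree_cfg: Mapping, values: Mapping[str, float]) -> DecisionNode:
    """Build a DecisionNode tree from config, resolving all expressions."""
    branches = []
    for b in tree_cfg.get("branches", []):
        prob = resolve_expression(b["probability"], values)
        cost = resolve_expression(b.get("cost", 0.0), values)
        if "terminal" in b:
            child = {
                k: resolve_expression(v, values) for k, v in b["terminal"].items()
            }
        else:
            child = decision_tree_from_config(b["node"], values)
        branches.append((prob, cost, child))
    return DecisionNode(label=str(tree_cfg.get("label", "node")), branches=branches)


@dataclass
class CaseModel:
    """A loaded case: parameter set, cycle plan, scenarios and builder."""

    name: str
    params: ParameterSet
    plan: CyclePlan
    scenarios: dict[str, dict[str, float]]
    config: dict

    def builder(self, values: Mapping[str, float]) -> ComparisonResult:
        """Evaluate both arms at a parameter vector and compare them."""
        return _evaluate_case(self.config, self.plan, values)

    def base_case(self) -> ComparisonResult:
        return self.builder(self.params.base_values())


def _evaluate_case(
    config: Mapping, plan: CyclePlan, values: Mapping[str, float]
) -> ComparisonResult:
    states_cfg = config["states"]
    names = [s["name"] for s in states_cfg]
    arms = {}
    for role in ("comparator", "intervention"):
        arm_cfg = config["arms"][role]
        model = state_model_from_config(
            states_cfg, arm_cfg, plan.cycle_length_years, values
        )
        upfront = resolve_expression(arm_cfg.get("upfront_cost", 0.0), values)
        if "tree" in arm_cfg:
            tree = decision_tree_from_config(arm_cfg["tree"], values)
            entry, tree_cost = rollback_tree(tree, names)
            upfront += tree_cost
        else:
            entry = {
                k: resolve_expression(v, values)
                for k, v in arm_cfg["entry"].items()
            }
        arms[role] = evaluate_arm(model, entry, plan, upfront_cost=upfront)
    return compare_arms(arms["comparator"], arms["intervention"])


def _data_dir() -> Path:
    return Path(__file__).parent / "data"


def available_cases() -> list[str]:
    return sorted(
        p.name for p in _data_dir().iterdir() if (p / "model.yaml").is_file()
    )


def load_case(name: str, params_path=None) -> CaseModel:
    """Load a packaged case bundle (``cll`` or ``crbsi``).

    ``params_path`` substitutes an external parameter table for the
    packaged one. Parameters without an explicit distribution get the
    kind-matched default derived from their base and range.
    """
    case_dir = _data_dir() / name
    if not (case_dir / "model.yaml").is_file():
        raise ValidationError(
            f"unknown case {name!r}; available: {available_cases()}"
        )
    config = yaml.safe_load((case_dir / "model.yaml").read_text())
    params = ParameterSet.read_csv(
        params_path if params_path is not None else case_dir / "parameters.csv"
    )
    from dataclasses import replace as _replace

    params = ParameterSet(
        _replace(p, distribution=p.default_distribution())
        if p.distribution is None
        else p
        for p in params
    )
    scenarios_file = case_dir / "scenarios.yaml"
    scenarios = (
        yaml.safe_load(scenarios_file.read_text()) if scenarios_file.is_file() else {}
    ) or {}
    plan_cfg = config["cycle_plan"]
    plan = CyclePlan(
        horizon_years=float(plan_cfg["horizon_years"]),
        cycle_length_years=float(plan_cfg["cycle_length_years"]),
        discount_rate_costs=float(plan_cfg.get("discount_rate_costs", 0.03)),
        discount_rate_effects=float(plan_cfg.get("discount_rate_effects", 0.03)),
        half_cycle_correction=bool(plan_cfg.get("half_cycle_correction", True)),
    )
    missing = _config_references(config) - set(params.names)
    if missing:
        raise ValidationError(
            f"case {name!r}: unresolved parameter bindings {sorted(missing)}"
        )
    return CaseModel(
        name=name, params=params, plan=plan, scenarios=scenarios, config=config
    )


def _expr_refs(expr) -> set[str]:
    """Parameter names referenced by a single config expression."""
    if isinstance(expr, str):
        return {expr}
    if isinstance(expr, Mapping) and len(expr) == 1:
        (op, arg), = expr.items()
        if op == "mix":
            out: set[str] = set()
            for w, v in arg:
                out |= _expr_refs(w) | _expr_refs(v)
            return out
        if op == "complement":
            return _expr_refs(arg)
        out = set()
        for v in arg:
            out |= _expr_refs(v)
        return out
    return set()


def _tree_refs(tree_cfg: Mapping) -> set[str]:
    out: set[str] = set()
    for b in tree_cfg.get("branches", []):
        out |= _expr_refs(b["probability"]) | _expr_refs(b.get("cost", 0.0))
        if "terminal" in b:
            for v in b["terminal"].values():
                out |= _expr_refs(v)
        else:
            out |= _tree_refs(b["node"])
    return out


def _config_references(config: Mapping) -> set[str]:
    """All parameter names an evaluation of ``config`` will look up."""
    out: set[str] = set()
    for arm_cfg in config["arms"].values():
        for edge in arm_cfg.get("transitions", []):
            out |= _expr_refs(edge["value"])
        for section in ("state_costs", "state_utilities"):
            for v in (arm_cfg.get(section) or {}).values():
                out |= _expr_refs(v)
        out |= _expr_refs(arm_cfg.get("upfront_cost", 0.0))
        if "tree" in arm_cfg:
            out |= _tree_refs(arm_cfg["tree"])
        else:
            for v in arm_cfg["entry"].values():
                out |= _expr_refs(v)
    return out


def build_cll_model(params: ParameterSet | Mapping[str, float]) -> ComparisonResult:
    """Evaluate the CLL watch-and-wait stratification case."""
    return _build_named("cll", params)


def build_crbsi_model(params: ParameterSet | Mapping[str, float]) -> ComparisonResult:
    """Evaluate the ICU CRBSI early-detection case."""
    return _build_named("crbsi", params)


def _build_named(name: str, params) -> ComparisonResult:
    case = load_case(name)
    if isinstance(params, ParameterSet):
        values = params.base_values()
    else:
        values = dict(params)
    missing = _config_references(case.config) - set(values)
    if missing:
        raise ValidationError(
            f"case {name!r}: missing parameter bindings {sorted(missing)}"
        )
    return case.builder(values)
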