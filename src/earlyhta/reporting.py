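"""Result rendering and run manifests.

``render_comparison_report`` produces the standard per-arm / incremental
/ ICER layout in two forms: a machine-readable table with unrounded
numbers and a human-readable text block with configurable display
rounding (default: whole currency units, two decimals for LY/QALYs).
A :class:`RunManifest` records everything needed to replay a run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

import pandas as pd

from .health_econ import ComparisonResult

__all__ = ["render_comparison_report", "comparison_frame", "RunManifest"]


def comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    """Machine-readable table: per-arm rows, incremental row, ICER row."""
    rows = [
        {
            "row": "comparator",
            "cost": result.comparator.total_cost,
            "life_years": result.comparator.life_years,
            "qalys": result.comparator.qalys,
        },
        {
            "row": "intervention",
            "cost": result.intervention.total_cost,
            "life_years": result.intervention.life_years,
            "qalys": result.intervention.qalys,
        },
        {
            "row": "incremental",
            "cost": result.delta_cost,
            "life_years": result.delta_ly,
            "qalys": result.delta_qaly,
        },
        {
            "row": "icer",
            "cost": float("nan"),
            "life_years": (
                result.icer_per_ly if result.icer_per_ly is not None else float("nan")
            ),
            "qalys": (
                result.icer_per_qaly
                if result.icer_per_qaly is not None
                else float("nan")
            ),
        },
    ]
    return pd.DataFrame(rows, columns=["row", "cost", "life_years", "qalys"])


def render_comparison_report(
    result: ComparisonResult,
    scenario_label: str = "base case",
    currency: str = "EUR",
    cost_decimals: int = 0,
    effect_decimals: int = 2,
) -> tuple[str, pd.DataFrame]:
    """Render a comparison as (human text, machine table).

    The machine table carries unrounded numbers; the text applies the
    configured display rounding. Undefined ICERs (zero incremental
    effect) render as explanatory text, never as infinities.
    """

    def money(x: float) -> str:
        return f"{x:,.{cost_decimals}f} {currency}"

    def eff(x: float) -> str:
        return f"{x:.{effect_decimals}f}"

    def icer(value: Optional[float], unit: str) -> str:
        if value is None:
            return f"undefined (no {unit} difference)"
        return f"{money(value)}/{unit}"

    lines = [
        f"Scenario: {scenario_label}",
        f"{'':<16}{'Costs':>18}{'Life years':>14}{'QALYs':>10}",
        (
            f"{'Comparator':<16}{money(result.comparator.total_cost):>18}"
            f"{eff(result.comparator.life_years):>14}"
            f"{eff(result.comparator.qalys):>10}"
        ),
        (
            f"{'Intervention':<16}{money(result.intervention.total_cost):>18}"
            f"{eff(result.intervention.life_years):>14}"
            f"{eff(result.intervention.qalys):>10}"
        ),
        (
            f"{'Incremental':<16}{money(result.delta_cost):>18}"
            f"{eff(result.delta_ly):>14}{eff(result.delta_qaly):>10}"
        ),
        f"ICER per life year: {icer(result.icer_per_ly, 'LY')}",
        f"ICER per QALY: {icer(result.icer_per_qaly, 'QALY')}",
        f"Dominance: {result.dominance_label}",
    ]
    return "\n".join(lines), comparison_frame(result)


@dataclass
class RunManifest:
    """What was run, with what, and what it produced."""

    case: str
    command: str
    config_paths: dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    package_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
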