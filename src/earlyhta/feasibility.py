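"""Data-feasibility audit and PICO scope/barrier ledger.

Before any economic evaluation is built, two gates apply:

1. *Data audit*: is the candidate development dataset of sufficient
   quantity and quality? The auditor computes descriptive metrics —
   sample size, median follow-up, per-field missingness, site count,
   outcome capture — and compares each against user-supplied
   requirements. The module encodes no clinical judgement: thresholds
   always come from the requirements, never from defaults.
2. *Scope ledger*: a PICO (Population, Intervention, Comparator,
   Outcomes) description plus a list of identified barriers, each graded
   surmountable or insurmountable. Development proceeds to evaluation
   only when no insurmountable barrier remains.

Follow-up is measured in years as (last contact - enrolment)/365.25;
rows where either date is missing or unparseable are excluded from the
median and reported separately as a follow-up-unknown fraction, so
missing dates can never make the median look better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ValidationError

__all__ = [
    "DataRequirement",
    "ColumnRoles",
    "RequirementVerdict",
    "DataAuditReport",
    "Barrier",
    "ScopeLedger",
    "ScopeVerdict",
    "audit_dataset",
    "evaluate_scope",
]

_METRICS = (
    "sample_size",
    "median_follow_up",
    "missingness_fraction",
    "site_count",
    "outcome_capture_fraction",
)

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class DataRequirement:
    """A quantitative requirement on one audit metric.

    ``metric='missingness_fraction'`` requires ``column`` to name the
    audited field. ``comparator`` is '>=' or '<='; the requirement passes
    when ``observed <comparator> threshold``.
    """

    metric: str
    comparator: str
    threshold: float
    column: Optional[str] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValidationError(
                f"unknown audit metric {self.metric!r}; expected one of {_METRICS}"
            )
        if self.comparator not in (">=", "<="):
            raise ValidationError(f"comparator must be '>=' or '<='")
        if not np.isfinite(self.threshold):
            raise ValidationError("requirement threshold must be finite")
        if self.metric in ("missingness_fraction", "outcome_capture_fraction"):
            if not 0.0 <= self.threshold <= 1.0:
                raise ValidationError(
                    f"{self.metric} threshold must be within [0, 1]"
                )
        if self.metric == "missingness_fraction" and not self.column:
            raise ValidationError(
                "missingness_fraction requirement needs a 'column'"
            )

    def check(self, observed: float) -> bool:
        if not np.isfinite(observed):
            return False
        if self.comparator == ">=":
            return observed >= self.threshold
        return observed <= self.threshold


@dataclass(frozen=True)
class ColumnRoles:
    """Which dataframe columns play which role in the audit."""

    enrolment_date: str = "enrolment_date"
    last_contact_date: str = "last_contact_date"
    site: Optional[str] = None
    outcome: Optional[str] = None


@dataclass(frozen=True)
class RequirementVerdict:
    requirement: DataRequirement
    observed: float
    passed: bool


@dataclass
class DataAuditReport:
    """Audit metrics, per-requirement verdicts and an overall gate.

    The overall verdict is 'not-feasible' iff at least one requirement
    fails; 'feasible' otherwise. Bias and representativeness are not
    assessed, only descriptive per-site stratification.
    """

    sample_size: int
    median_follow_up_years: float
    follow_up_unknown_fraction: float
    missingness: dict[str, float]
    site_count: int
    outcome_capture_fraction: float
    per_site: Optional[pd.DataFrame]
    verdicts: list[RequirementVerdict]
    narrative: list[str] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def overall_verdict(self) -> str:
        return "feasible" if self.feasible else "not-feasible"

    def metric_value(self, req: DataRequirement) -> float:
        if req.metric == "sample_size":
            return float(self.sample_size)
        if req.metric == "median_follow_up":
            return self.median_follow_up_years
        if req.metric == "missingness_fraction":
            return self.missingness.get(req.column, float("nan"))
        if req.metric == "site_count":
            return float(self.site_count)
        return self.outcome_capture_fraction

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": v.requirement.metric,
                "column": v.requirement.column or "",
                "comparator": v.requirement.comparator,
                "threshold": v.requirement.threshold,
                "observed": v.observed,
                "verdict": "pass" if v.passed else "fail",
            }
            for v in self.verdicts
        ]
        return pd.DataFrame(
            rows,
            columns=["metric", "column", "comparator", "threshold", "observed", "verdict"],
        )

    def to_text(self) -> str:
        lines = list(self.narrative)
        for v in self.verdicts:
            col = f" [{v.requirement.column}]" if v.requirement.column else ""
            lines.append(
                f"{'PASS' if v.passed else 'FAIL'}: {v.requirement.metric}{col} "
                f"= {v.observed:.4g} (required {v.requirement.comparator} "
                f"{v.requirement.threshold:g})"
            )
        lines.append(f"Overall verdict: {self.overall_verdict}")
        return "\n".join(lines)


def _parse_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, errors="coerce", format="mixed")


def audit_dataset(
    records: pd.DataFrame,
    roles: ColumnRoles,
    requirements: Sequence[DataRequirement] = (),
) -> DataAuditReport:
    """Audit a patient-level table against quantitative requirements.

    Sample size is the row count; follow-up per patient is last contact
    minus enrolment (unparseable dates count as missing, never fatal);
    missingness per field is the fraction of absent values.
    """
    for col in (roles.enrolment_date, roles.last_contact_date):
        if col not in records.columns:
            raise ValidationError(f"role column {col!r} not in table")
    for col in (roles.site, roles.outcome):
        if col is not None and col not in records.columns:
            raise ValidationError(f"role column {col!r} not in table")

    n = len(records)
    narrative: list[str] = [f"Audited {n} patient records."]

    enrol = _parse_dates(records[roles.enrolment_date])
    last = _parse_dates(records[roles.last_contact_date])
    fu_years = (last - enrol).dt.days / _DAYS_PER_YEAR
    known = fu_years.notna()
    median_fu = float(fu_years[known].median()) if known.any() else float("nan")
    unknown_frac = float(1.0 - known.mean()) if n else 0.0
    if unknown_frac > 0:
        narrative.append(
            f"Follow-up unknown (missing/unparseable dates) for "
            f"{unknown_frac:.1%} of patients; they are excluded from the "
            "median follow-up."
        )

    missingness = {
        col: (float(records[col].isna().mean()) if n else 0.0)
        for col in records.columns
    }
    # date columns: unparseable strings are as good as absent
    missingness[roles.enrolment_date] = float(enrol.isna().mean()) if n else 0.0
    missingness[roles.last_contact_date] = float(last.isna().mean()) if n else 0.0

    if roles.site is not None:
        sites = records[roles.site]
        site_count = int(sites.nunique(dropna=True))
        per_site = (
            records.assign(_fu=fu_years)
            .groupby(roles.site, dropna=True)
            .agg(n=(roles.site, "size"), median_follow_up_years=("_fu", "median"))
            .reset_index()
        )
    else:
        site_count = 1
        per_site = None

    if roles.outcome is not None and n:
        capture = float(records[roles.outcome].notna().mean())
    else:
        capture = float("nan") if roles.outcome is not None else 1.0

    report = DataAuditReport(
        sample_size=n,
        median_follow_up_years=median_fu,
        follow_up_unknown_fraction=unknown_frac,
        missingness=missingness,
        site_count=site_count,
        outcome_capture_fraction=capture,
        per_site=per_site,
        verdicts=[],
        narrative=narrative,
    )
    for req in requirements:
        observed = report.metric_value(req)
        report.verdicts.append(
            RequirementVerdict(
                requirement=req, observed=observed, passed=req.check(observed)
            )
        )
    report.narrative.append(
        "Bias and representativeness: not assessed (descriptive audit only)."
    )
    return report


@dataclass(frozen=True)
class Barrier:
    """A development/implementation barrier with a severity grade."""

    description: str
    severity: str  # 'surmountable' | 'insurmountable'

    def __post_init__(self) -> None:
        if self.severity not in ("surmountable", "insurmountable"):
            raise ValidationError(
                f"barrier severity must be 'surmountable' or 'insurmountable', "
                f"got {self.severity!r}"
            )


@dataclass
class ScopeLedger:
    """PICO scope description plus identified barriers."""

    population: str
    intervention: str
    comparator: str
    outcomes: str
    barriers: list[Barrier] = field(default_factory=list)


@dataclass(frozen=True)
class ScopeVerdict:
    decision: str  # 'proceed-to-evaluation' | 're-scope-or-cease'
    blocking_barriers: tuple[Barrier, ...]
    surmountable_barriers: tuple[Barrier, ...]


def evaluate_scope(ledger: ScopeLedger) -> ScopeVerdict:
    """Gate on the scope ledger: proceed iff no insurmountable barrier.

    Surmountable barriers do not block; they are echoed so the evaluation
    can carry them as scenarios. Whether an insurmountable barrier means
    re-scoping or ceasing altogether is a developer decision, so the
    blocking verdict is 're-scope-or-cease'.
    """
    for fname in ("population", "intervention", "comparator", "outcomes"):
        if not str(getattr(ledger, fname)).strip():
            raise ValidationError(f"PICO field {fname!r} is empty")
    blocking = tuple(b for b in ledger.barriers if b.severity == "insurmountable")
    surmountable = tuple(b for b in ledger.barriers if b.severity == "surmountable")
    decision = "proceed-to-evaluation" if not blocking else "re-scope-or-cease"
    return ScopeVerdict(
        decision=decision,
        blocking_barriers=blocking,
        surmountable_barriers=surmountable,
    )
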