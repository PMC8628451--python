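"""Synthetic inputs: parameter tables and EHR-like patient tables.

Everything the pipeline consumes can be generated here, seeded and
bit-reproducible:

- parameter sets with the statistical structure of an early-evaluation
  input table — beta-distributed probabilities and utilities,
  gamma-distributed costs, lognormally distributed hazard ratios — each
  with a base value, a containing (low, high) range and a kind-matched
  sampling distribution;
- patient-level tables (enrolment/last-contact dates, site, outcome and
  covariate fields) with configurable sample size, follow-up
  distribution and per-field missing-completely-at-random rates, so the
  feasibility auditor can be exercised against known ground truth
  (including the small-sample / heavy-missing-follow-up pathology).

Follow-up durations default to an exponential distribution, censored at
an administrative cutoff. Informative (non-random) missingness and
correlated clinical covariates are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import spec_from_range
from .engine import ValidationError
from .health_econ import ParameterSet, ParameterValue

__all__ = [
    "ParameterGeneratorConfig",
    "PatientTableConfig",
    "generate_parameter_set",
    "generate_patient_table",
]


@dataclass(frozen=True)
class ParameterGeneratorConfig:
    """Counts per parameter kind and plausible sampling ranges."""

    seed: int = 0
    n_probabilities: int = 4
    n_utilities: int = 3
    n_costs: int = 4
    n_hazard_ratios: int = 1
    probability_range: tuple[float, float] = (0.01, 0.5)
    utility_range: tuple[float, float] = (0.4, 0.95)
    cost_range: tuple[float, float] = (50.0, 10_000.0)
    hazard_ratio_range: tuple[float, float] = (0.2, 1.5)

    def __post_init__(self) -> None:
        for n in (self.n_probabilities, self.n_utilities, self.n_costs,
                  self.n_hazard_ratios):
            if n < 0:
                raise ValidationError("parameter counts must be non-negative")


def generate_parameter_set(config: ParameterGeneratorConfig) -> ParameterSet:
    """Draw a seeded, self-consistent parameter table.

    Each parameter's base value is drawn uniformly within its kind's
    configured range; the (low, high) bounds bracket it at roughly
    +/- 25% (clipped to the kind support) and the distribution is the
    kind-matched method-of-moments spec, so every generated parameter
    passes downstream validation unchanged.
    """
    rng = np.random.default_rng(config.seed)
    values: list[ParameterValue] = []

    def add(prefix: str, kind: str, n: int, lo: float, hi: float,
            support: tuple[float, float]) -> None:
        for i in range(n):
            base = float(rng.uniform(lo, hi))
            spread = 0.25 * base if base > 0 else 0.1
            low = max(support[0], base - spread)
            high = min(support[1], base + spread)
            if kind == "hazard-ratio":
                low = max(low, 1e-6)
            pv = ParameterValue(
                name=f"{prefix}_{i + 1}",
                kind=kind,
                base=base,
                low=low,
                high=high,
                source_tag="assumption",
            )
            values.append(
                ParameterValue(
                    **{**pv.__dict__, "distribution": pv.default_distribution()}
                )
            )

    add("p", "probability", config.n_probabilities,
        *config.probability_range, (0.0, 1.0))
    add("u", "utility", config.n_utilities, *config.utility_range, (0.0, 1.0))
    add("c", "cost", config.n_costs, *config.cost_range, (0.0, np.inf))
    add("hr", "hazard-ratio", config.n_hazard_ratios,
        *config.hazard_ratio_range, (1e-6, np.inf))
    return ParameterSet(values)


@dataclass(frozen=True)
class PatientTableConfig:
    """Shape of a synthetic EHR-like patient table.

    ``missingness`` maps column names to independent MCAR rates in
    [0, 1]; ``followup_mean_years`` parametrises the exponential
    follow-up distribution, administratively censored at
    ``admin_censor_years`` after enrolment.
    """

    seed: int = 0
    n_patients: int = 500
    n_sites: int = 3
    enrolment_start: str = "2015-01-01"
    enrolment_window_years: float = 2.0
    followup_mean_years: float = 3.0
    admin_censor_years: float = 6.0
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.followup_mean_years <= 0 or self.admin_censor_years <= 0:
            raise ValidationError("follow-up durations must be positive")
        for col, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(
                    f"missingness rate for {col!r} must be within [0, 1]"
                )


#: columns every generated patient table carries
PATIENT_COLUMNS = (
    "patient_id",
    "site",
    "enrolment_date",
    "last_contact_date",
    "age",
    "sex",
    "outcome",
)


def generate_patient_table(config: PatientTableConfig) -> pd.DataFrame:
    """Generate a seeded patient-level table with known pathology.

    Dates are ISO strings (the auditor parses them); each field listed in
    ``config.missingness`` is masked to missing independently at its
    configured rate after generation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.enrolment_start)

    enrol_offset_days = rng.uniform(
        0, config.enrolment_window_years * 365.25, size=n
    )
    followup_years = rng.exponential(config.followup_mean_years, size=n)
    followup_years = np.minimum(followup_years, config.admin_censor_years)

    enrolment = start + pd.to_timedelta(np.round(enrol_offset_days), unit="D")
    last_contact = enrolment + pd.to_timedelta(
        np.round(followup_years * 365.25), unit="D"
    )

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "site": rng.integers(1, config.n_sites + 1, size=n).astype(str),
            "enrolment_date": enrolment.strftime("%Y-%m-%d"),
            "last_contact_date": last_contact.strftime("%Y-%m-%d"),
            "age": np.round(rng.normal(68, 10, size=n)).clip(18, 100),
            "sex": rng.choice(["F", "M"], size=n),
            "outcome": rng.choice(["progression", "stable", "death"], size=n,
                                  p=[0.3, 0.55, 0.15]),
        }
    )
    df["site"] = "S" + df["site"]
    for col, rate in config.missingness.items():
        if col not in df.columns:
            raise ValidationError(f"missingness configured for unknown column {col!r}")
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, col] = np.nan
    return df
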