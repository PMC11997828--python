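"""Domain types and configuration registry for trial-based benefit-cost analysis.

Every economic symbol used downstream (discount rate r, growth rate g, income
elasticity e, overlap weight w, persistence horizons T1, life expectancy at
age two T2, the VSL ratio and VSLY divisor, phase unit costs and participant
counts) resolves to exactly one field on the types defined here.

Sign convention: absolute risk reductions (ARR) are stored in percentage
points with *positive = fewer adverse events* (risk in the control arm minus
risk in the intervention arm). Published tables often print the raw risk
difference (intervention minus control, negative = reduction); transcribe
those with the sign flipped. Mean differences for continuous outcomes are
stored as printed (positive = improvement).
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class Period(str, Enum):
    """Trial phase in which an outcome is measured."""

    preconception = "preconception"
    pregnancy = "pregnancy"
    childhood = "childhood"


class Comparison(str, Enum):
    """Intervention group versus routine care.

    B = preconception package only; C = pregnancy and early-childhood
    package only; A = full package (both randomizations to intervention).
    """

    B_vs_control = "B_vs_control"
    C_vs_control = "C_vs_control"
    A_vs_control = "A_vs_control"


class Metric(str, Enum):
    ARR_percent = "ARR_percent"
    mean_difference = "mean_difference"


class Beneficiary(str, Enum):
    woman = "woman"
    child = "child"


class Channel(str, Enum):
    mortality = "mortality"
    morbidity = "morbidity"
    productivity = "productivity"


class Phase(str, Enum):
    preconception = "preconception"
    pregnancy = "pregnancy"
    early_childhood = "early_childhood"


#: Ingredient components of the delivery cost ledger, one column per domain.
COST_COMPONENTS = (
    "consumables",
    "equipment",
    "health",
    "human_resource",
    "nutrition",
    "psychosocial",
    "transport",
    "wash",
)


class EffectEstimate(BaseModel):
    """One outcome's effect size for one comparison.

    ``point`` is the ARR in percentage points (positive = risk reduced) or
    the mean difference in the outcome's own unit. Confidence intervals are
    orientation-normalized on ingest so ``ci_low <= point <= ci_high`` always
    holds, regardless of the order the source table printed the endpoints in.
    """

    outcome_id: str
    period: Period
    comparison: Comparison
    metric: Metric
    point: float
    ci_low: float
    ci_high: float
    ci_level: float = Field(default=0.983, gt=0.0, lt=1.0)

    @model_validator(mode="before")
    @classmethod
    def _orient_interval(cls, data):
        if isinstance(data, dict):
            lo, hi = data.get("ci_low"), data.get("ci_high")
            if lo is not None and hi is not None and lo > hi:
                data["ci_low"], data["ci_high"] = hi, lo
        return data

    @model_validator(mode="after")
    def _check(self) -> "EffectEstimate":
        if not (self.ci_low - 1e-9 <= self.point <= self.ci_high + 1e-9):
            raise ValueError(
                f"{self.outcome_id}: point {self.point} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )
        if self.metric is Metric.ARR_percent:
            if not (-100.0 <= self.point <= 100.0):
                raise ValueError(
                    f"{self.outcome_id}: ARR {self.point}% outside [-100, 100]"
                )
        return self


class OutcomeSpec(BaseModel):
    """Valuation routing for one outcome: who benefits and through which channel.

    Exactly one channel applies per outcome. Morbidity outcomes need a GBD
    disability weight and a persistence horizon T1 (years; fractions allowed,
    e.g. 1.5 y for conditions resolved over preconception plus pregnancy).
    Productivity outcomes need the fraction ``f`` of discounted lifetime
    earnings gained per unit of effect. ``report_as`` groups several valued
    strata (e.g. mild/moderate/severe anaemia) into one reporting row.
    """

    outcome_id: str
    beneficiary: Beneficiary
    channel: Channel
    disability_weight: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    persistence_years: Optional[float] = Field(default=None, gt=0.0)
    productivity_fraction: Optional[float] = None
    report_as: Optional[str] = None

    @model_validator(mode="after")
    def _channel_requirements(self) -> "OutcomeSpec":
        if self.channel is Channel.morbidity:
            if self.disability_weight is None or self.persistence_years is None:
                raise ValueError(
                    f"{self.outcome_id}: morbidity outcomes require "
                    "disability_weight and persistence_years"
                )
        if self.channel is Channel.productivity and self.productivity_fraction is None:
            raise ValueError(
                f"{self.outcome_id}: productivity outcomes require productivity_fraction"
            )
        return self

    @property
    def report_key(self) -> str:
        return self.report_as or self.outcome_id


class ParticipantFlow(BaseModel):
    """Counts of women/pregnancies/children used for per-dyad cost scaling."""

    n_preconception: int = Field(ge=0)
    n_pregnancy: int = Field(ge=0)
    n_children_24m: int = Field(ge=0)

    @model_validator(mode="after")
    def _monotone(self) -> "ParticipantFlow":
        if not (self.n_preconception >= self.n_pregnancy >= self.n_children_24m):
            raise ValueError(
                "participant flow must satisfy "
                "n_preconception >= n_pregnancy >= n_children_24m"
            )
        return self


class EconParams(BaseModel):
    """Economic parameters of the monetization model.

    VSL = ``gni_pc_ppp * vsl_ratio`` (ratio 100, income elasticity 1, no age
    adjustment); VSLY = VSL / ``vsly_divisor`` (35 productive years). One
    DALY is valued at one VSLY. ``overlap_weight`` (w = 0.6) deflates the sum
    of productivity pathways that operate through overlapping mechanisms.
    ``vsl_override``/``vsly_override`` exist for one-way sensitivity
    scenarios that vary VSL or VSLY independently of their derivation.
    """

    gni_pc_ppp: float = Field(gt=0.0)
    vsl_ratio: float = Field(default=100.0, gt=0.0)
    income_elasticity: float = 1.0
    vsly_divisor: float = Field(default=35.0, gt=0.0)
    discount_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    growth_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    life_expectancy_at_2: float = Field(default=70.0, gt=0.0)
    earnings_start_age: float = Field(default=18.0, ge=0.0)
    working_years: int = Field(default=35, gt=0)
    overlap_weight: float = Field(default=0.6, gt=0.0, le=1.0)
    ppp_per_inr: float = Field(default=1.0 / 23.13, gt=0.0)
    baseline_earnings: Optional[float] = Field(default=None, gt=0.0)
    healthcare_savings_per_dyad: float = 0.0
    discount_mortality: bool = False
    discount_morbidity: bool = False
    vsl_override: Optional[float] = Field(default=None, gt=0.0)
    vsly_override: Optional[float] = Field(default=None, gt=0.0)


class PhaseUnitCost(BaseModel):
    """Per-participant delivery cost of one phase, itemized by component."""

    phase: Phase
    component_costs: dict[str, float]
    duration_months: float = Field(gt=0.0)

    @field_validator("component_costs")
    @classmethod
    def _components(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COST_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown cost components: {sorted(unknown)}")
        if any(c < 0 for c in v.values()):
            raise ValueError("component costs must be >= 0")
        return {c: float(v.get(c, 0.0)) for c in COST_COMPONENTS}


class MonetaryBenefit(BaseModel):
    """Per-dyad monetary value of one outcome's effect (may be negative)."""

    outcome_id: str
    comparison: Comparison
    value: float

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("benefit value must be finite")
        return v


class BCAResult(BaseModel):
    """Benefits, costs, BCR and NMB for one comparison, with breakdown."""

    comparison: Comparison
    total_benefit: float
    incremental_cost: float
    bcr: float
    nmb: float
    breakdown: list[MonetaryBenefit]

    @model_validator(mode="after")
    def _consistent(self) -> "BCAResult":
        s = sum(b.value for b in self.breakdown)
        if abs(s - self.total_benefit) > 1e-6 * max(1.0, abs(self.total_benefit)):
            raise ValueError("total_benefit must equal the sum of its breakdown")
        if abs(self.nmb - (self.total_benefit - self.incremental_cost)) > 1e-9 * max(
            1.0, abs(self.total_benefit)
        ):
            raise ValueError("nmb must equal total_benefit - incremental_cost")
        return self


class StudyBundle(BaseModel):
    """Validated bundle of everything one analysis run consumes."""

    econ_params: EconParams
    participant_flow: ParticipantFlow
    effects: list[EffectEstimate]
    outcome_specs: list[OutcomeSpec]
    unit_costs: list[PhaseUnitCost]

    @model_validator(mode="after")
    def _cross_check(self) -> "StudyBundle":
        known = {s.outcome_id for s in self.outcome_specs}
        orphans = sorted({e.outcome_id for e in self.effects} - known)
        if orphans:
            raise ValueError(f"effects without an OutcomeSpec: {orphans}")
        phases = [c.phase for c in self.unit_costs]
        if len(phases) != len(set(phases)):
            raise ValueError("duplicate phase in unit_costs")
        return self

    @property
    def spec_map(self) -> dict[str, OutcomeSpec]:
        return {s.outcome_id: s for s in self.outcome_specs}

    def effects_for(self, comparison: Comparison) -> list[EffectEstimate]:
        return [e for e in self.effects if e.comparison == comparison]

    def unit_cost(self, phase: Phase) -> PhaseUnitCost:
        for c in self.unit_costs:
            if c.phase == phase:
                return c
        raise KeyError(f"no unit cost for phase {phase.value}")


# ---------------------------------------------------------------------------
# Loading / serialization


def load_study_config(path: str | Path) -> StudyBundle:
    """Load and validate a study configuration (YAML or JSON).

    The document has sections ``econ_params``, ``participant_flow``,
    ``effects``, ``outcome_specs`` and ``unit_costs``; YAML is a superset of
    JSON, so both dialects parse. Validation errors name the offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return StudyBundle.model_validate(data)


def serialize_study_config(bundle: StudyBundle, path: str | Path) -> None:
    """Write a bundle back to YAML; ``load_study_config`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.model_dump(mode="json"), fh, sort_keys=False)


def effects_from_csv(path: str | Path) -> list[EffectEstimate]:
    """Read effects from CSV with headers
    (outcome_id, period, comparison, metric, point, ci_low, ci_high[, ci_level])."""
    df = pd.read_csv(path)
    rows = df.to_dict(orient="records")
    return [EffectEstimate.model_validate(r) for r in rows]


def unit_costs_from_csv(path: str | Path) -> list[PhaseUnitCost]:
    """Read a long-format unit-cost ledger with headers
    (phase, component, cost, duration_months)."""
    df = pd.read_csv(path)
    out: list[PhaseUnitCost] = []
    for phase, grp in df.groupby("phase", sort=False):
        durations = grp["duration_months"].unique()
        if len(durations) != 1:
            raise ValueError(f"phase {phase}: inconsistent duration_months")
        out.append(
            PhaseUnitCost(
                phase=Phase(phase),
                component_costs=dict(zip(grp["component"], grp["cost"])),
                duration_months=float(durations[0]),
            )
        )
    return out


def load_packaged_study() -> StudyBundle:
    """Load the packaged fixture: the Delhi factorial preconception/pregnancy/
    early-childhood trial, transcribed from its published effect and cost
    tables with calibrated valuation parameters (see the package docs)."""
    ref = resources.files("mchbca").joinpath("data/delhi_trial.yaml")
    with resources.as_file(ref) as p:
        return load_study_config(p)


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero — the convention of the published tables.

    Internal arithmetic is full precision; call this only at the reporting
    boundary.
    """
    q = 10.0**ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1.0 if x >= 0 else -1.0)
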