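"""Ingredient-based costing: phase unit costs and per-dyad incremental costs.

The provider-perspective incremental cost identity is
``(cost of interventions + cost of routine care) - cost of routine care``:
both arms use the public system equally, so routine-care utilization cancels
and no routine-care cost input is required.

Per-dyad incremental unit costs scale each phase's unit cost by the ratio of
participants who received that phase to children followed to 24 months:

* group B (preconception only):  ``UC_pre * N_pre / N_child``
* group C (pregnancy + early childhood): ``UC_preg * N_preg / N_child + UC_ec``
* group A (full package): B + C

The published formula table repeats the preconception term inside group C,
which would make C and A identical; the published per-dyad costs are only
consistent with C excluding it, so the excluded form is the default and the
printed form sits behind ``include_preconception_in_group_c``.
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import math

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core_model import (
    COST_COMPONENTS,
    EconParams,
    ParticipantFlow,
    Phase,
    PhaseUnitCost,
    round_report,
)


class CostGroup(str, Enum):
    B_preconception = "B_preconception"
    C_pregnancy_ec = "C_pregnancy_ec"
    A_full = "A_full"


class SharedCostAllocation(BaseModel):
    """A cost item shared across phases/groups, split by utilization share."""

    item_id: str
    total_cost: float = Field(ge=0.0)
    utilization_fractions: dict[str, float]

    @model_validator(mode="after")
    def _fractions(self) -> "SharedCostAllocation":
        if any(f < 0 for f in self.utilization_fractions.values()):
            raise ValueError(f"{self.item_id}: utilization fractions must be >= 0")
        total = sum(self.utilization_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.item_id}: utilization fractions sum to {total}, not 1"
            )
        return self


def phase_total(cost: PhaseUnitCost) -> float:
    """Sum of the eight component costs of one phase."""
    return sum(cost.component_costs.values())


def component_shares(cost: PhaseUnitCost) -> dict[str, float]:
    """Each component's share of the phase total, in percent."""
    total = phase_total(cost)
    if total <= 0:
        raise ValueError(f"{cost.phase.value}: phase total must be > 0 for shares")
    return {c: 100.0 * v / total for c, v in cost.component_costs.items()}


def cost_per_month(cost: PhaseUnitCost) -> float:
    """Average delivery cost per month of the phase."""
    return phase_total(cost) / cost.duration_months


def apportion_shared(item: SharedCostAllocation) -> dict[str, float]:
    """Split a shared cost by utilization fraction, conserving the total exactly.

    All but one allocation is ``total * fraction``; the key with the largest
    fraction (first on ties, returned last) absorbs the floating-point
    residual. If round-to-even makes the exact total unreachable by adjusting
    the absorber alone, the largest other share is nudged by ulps to shift
    the rounding lattice; summing the returned allocations in iteration
    order then reproduces ``total_cost`` bit-exactly.
    """
    fractions = item.utilization_fractions
    keys = list(fractions)
    if not keys:
        return {}
    total = item.total_cost
    absorber = max(keys, key=lambda k: fractions[k])
    others = [k for k in keys if k != absorber]

    def running_sum(vals: dict[str, float]) -> float:
        s = 0.0
        for k in others:
            s += vals[k]
        return s

    def solve_last(running: float) -> Optional[float]:
        """Find x with fl(running + x) == total via error feedback; the
        target can be unreachable (round-to-even skips it), then None."""
        last, prev = total - running, None
        for _ in range(20):
            err = (running + last) - total
            if err == 0.0:
                return last
            step = last - err
            if step == last:
                step = math.nextafter(last, -math.inf if err > 0 else math.inf)
            if step == prev:
                return None
            prev, last = last, step
        return None

    base = {k: total * fractions[k] for k in others}

    def candidates():
        yield dict(base)
        if not others:
            return
        # nudging the smallest share gives the finest control: the rounded
        # running sum then walks consecutive floats (both mantissa parities)
        base_running = running_sum(base)
        for pivot in sorted(others, key=lambda k: abs(base[k])):
            for direction in (math.inf, -math.inf):
                cand, seen = dict(base), {base_running}
                for _ in range(256):
                    cand = dict(cand)
                    cand[pivot] = math.nextafter(cand[pivot], direction)
                    r = running_sum(cand)
                    if r not in seen:
                        seen.add(r)
                        yield cand
                    if len(seen) > 4:
                        break

    for cand in candidates():
        last = solve_last(running_sum(cand))
        if last is not None:
            cand[absorber] = last
            return cand
    raise ArithmeticError(  # pragma: no cover - not observed in practice
        f"{item.item_id}: could not conserve total exactly"
    )


def inr_to_ppp(amount_inr: float, params: EconParams) -> float:
    """Convert Indian rupees to PPP international dollars (1 $PPP = 23.13 INR)."""
    if amount_inr < 0:
        raise ValueError("amount must be >= 0")
    return amount_inr * params.ppp_per_inr


def incremental_unit_cost(
    group: CostGroup,
    costs: list[PhaseUnitCost],
    flow: ParticipantFlow,
    discount_rate: float = 0.0,
    timing: Optional[Mapping[Phase, float]] = None,
    include_preconception_in_group_c: bool = False,
    child_exposure_weight: float = 1.0,
) -> float:
    """Per-dyad incremental cost of one comparison group, in $PPP.

    ``timing`` maps each phase to its time offset in years; phase costs are
    discounted by ``(1+r)^-offset``. The default (no offsets) reproduces the
    published per-dyad costs, which show no relative discounting across the
    4-year delivery window. ``child_exposure_weight`` scales the early
    childhood unit cost for truncated exposure (children who died are costed
    to their average age at death).
    """
    if flow.n_children_24m <= 0:
        raise ValueError("n_children_24m must be > 0 for per-dyad costs")
    timing = dict(timing or {})
    uc = {c.phase: phase_total(c) for c in costs}

    def disc(phase: Phase) -> float:
        return (1.0 + discount_rate) ** (-timing.get(phase, 0.0))

    b = uc[Phase.preconception] * disc(Phase.preconception) * (
        flow.n_preconception / flow.n_children_24m
    )
    c = uc[Phase.pregnancy] * disc(Phase.pregnancy) * (
        flow.n_pregnancy / flow.n_children_24m
    ) + uc[Phase.early_childhood] * disc(Phase.early_childhood) * child_exposure_weight

    if group is CostGroup.B_preconception:
        return b
    if group is CostGroup.C_pregnancy_ec:
        return c + b if include_preconception_in_group_c else c
    return b + c  # A = B + C (corrected group C form)


def unit_cost_table(costs: list[PhaseUnitCost]) -> pd.DataFrame:
    """Component-by-phase cost matrix with % shares, totals and cost/month,
    rounded for reporting (1 dp)."""
    cols = {}
    for c in sorted(costs, key=lambda c: list(Phase).index(c.phase)):
        shares = component_shares(c)
        col = {
            comp: f"{round_report(c.component_costs[comp])} ({round_report(shares[comp])})"
            for comp in COST_COMPONENTS
        }
        col["total"] = round_report(phase_total(c))
        col["duration_months"] = c.duration_months
        col["avg_cost_per_month"] = round_report(cost_per_month(c))
        cols[c.phase.value] = col
    return pd.DataFrame(cols)


def write_unit_cost_table(costs: list[PhaseUnitCost], path: str | Path) -> None:
    unit_cost_table(costs).to_csv(path, index_label="component")
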