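"""Assembly of benefit totals and incremental costs into BCR and NMB."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .benefit_valuation import value_all_benefits
from .core_model import (
    BCAResult,
    Comparison,
    MonetaryBenefit,
    Period,
    StudyBundle,
    round_report,
)
from .costing import CostGroup, incremental_unit_cost

logger = logging.getLogger(__name__)

#: Comparison -> cost group receiving that package.
COST_GROUP_FOR = {
    Comparison.B_vs_control: CostGroup.B_preconception,
    Comparison.C_vs_control: CostGroup.C_pregnancy_ec,
    Comparison.A_vs_control: CostGroup.A_full,
}

COMPARISON_ORDER = (
    Comparison.B_vs_control,
    Comparison.C_vs_control,
    Comparison.A_vs_control,
)


def bcr(total_benefit: float, incremental_cost: float) -> float:
    """Benefit-cost ratio. A nonpositive cost signals degenerate costing and
    raises; a negative total benefit yields a (reported) negative BCR."""
    if incremental_cost <= 0:
        raise ValueError("incremental cost must be > 0 for a BCR")
    return total_benefit / incremental_cost


def nmb(total_benefit: float, incremental_cost: float) -> float:
    """Net monetary benefit: benefits minus costs, both per dyad."""
    return total_benefit - incremental_cost


def run_full_analysis(
    bundle: StudyBundle, include_preconception_in_group_c: bool = False
) -> list[BCAResult]:
    """End-to-end analysis: one BCAResult per comparison (B, C, A vs routine
    care), breakdown rows in the order the effects were supplied."""
    try:
        benefits, totals = value_all_benefits(
            bundle.effects, bundle.outcome_specs, bundle.econ_params
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise type(exc)(f"[benefit valuation] {exc}") from exc

    results: list[BCAResult] = []
    for comp in COMPARISON_ORDER:
        if comp not in totals:
            continue
        try:
            cost = incremental_unit_cost(
                COST_GROUP_FOR[comp],
                bundle.unit_costs,
                bundle.participant_flow,
                discount_rate=bundle.econ_params.discount_rate,
                include_preconception_in_group_c=include_preconception_in_group_c,
            )
        except Exception as exc:  # noqa: BLE001
            raise type(exc)(f"[costing] {exc}") from exc
        total = totals[comp]
        if total < 0:
            logger.warning("%s: negative total benefit (%.1f)", comp.value, total)
        results.append(
            BCAResult(
                comparison=comp,
                total_benefit=total,
                incremental_cost=cost,
                bcr=bcr(total, cost),
                nmb=nmb(total, cost),
                breakdown=[b for b in benefits if b.comparison == comp],
            )
        )
    return results


def aggregate_breakdown(result: BCAResult, bundle: StudyBundle) -> list[tuple[str, float]]:
    """Collapse valuation strata into reporting rows (e.g. anaemia severities
    into one 'anaemia' row), preserving first-appearance order."""
    spec_map = bundle.spec_map
    rows: dict[str, float] = {}
    for b in result.breakdown:
        spec = spec_map.get(b.outcome_id)
        key = spec.report_key if spec is not None else b.outcome_id
        rows[key] = rows.get(key, 0.0) + b.value
    return list(rows.items())


def results_frame(results: list[BCAResult]) -> pd.DataFrame:
    """Headline table (one row per comparison), rounded for reporting."""
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison.value,
                "benefits": round_report(r.total_benefit),
                "costs": round_report(r.incremental_cost),
                "bcr": round_report(r.bcr),
                "nmb": round_report(r.nmb),
            }
            for r in results
        ]
    )


def breakdown_frame(results: list[BCAResult], bundle: StudyBundle) -> pd.DataFrame:
    """Per-outcome benefit matrix (reporting rows x comparisons, 1 dp),
    with each outcome's measurement period alongside."""
    period_for: dict[str, str] = {}
    for e in bundle.effects:
        spec = bundle.spec_map.get(e.outcome_id)
        key = spec.report_key if spec is not None else e.outcome_id
        period_for.setdefault(key, e.period.value)
    cols: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for r in results:
        for key, value in aggregate_breakdown(r, bundle):
            cols.setdefault(r.comparison.value, {})[key] = round_report(value)
            if key not in order:
                order.append(key)
    df = pd.DataFrame(cols).reindex(order)
    df.insert(0, "period", [period_for.get(k, "") for k in df.index])
    df.index.name = "outcome"
    return df


def write_results(
    results: list[BCAResult], bundle: StudyBundle, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(out / "results.csv", index=False)
    breakdown_frame(results, bundle).to_csv(out / "breakdown.csv")
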