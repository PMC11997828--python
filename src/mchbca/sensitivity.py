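"""One-way (tornado) sensitivity analysis over named model parameters.

Each scenario parameter carries a low/base/best triple; the analysis re-runs
the full pipeline with exactly one parameter swapped at a time and reports
the BCR at each value, rows sorted by descending BCR range (ties broken
alphabetically). Resolvable parameter names:

* ``effect:<outcome_id>`` - that outcome's effect point for the analysed
  comparison (low/best cases conventionally the multiplicity-adjusted CI
  endpoints);
* ``discount_rate`` / ``growth_rate`` - the economic rates;
* ``vsl`` / ``vsly`` - override the derived values for the scenario only;
* ``cost_scale`` - multiplies every unit-cost component.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from pydantic import BaseModel

from .bca_engine import run_full_analysis
from .core_model import Comparison, StudyBundle


class ScenarioParam(BaseModel):
    """Low/base/best values for one named parameter. 'low' should worsen the
    BCR; rows are re-oriented after evaluation if it does not."""

    name: str
    low: float
    base: float
    best: float


class TornadoRow(BaseModel):
    name: str
    bcr_low: float
    bcr_base: float
    bcr_best: float
    range: float


def _apply(bundle: StudyBundle, name: str, value: float, comparison: Comparison) -> StudyBundle:
    """Return a copy of the bundle with one parameter set to ``value``."""
    b = bundle.model_copy(deep=True)
    if name.startswith("effect:"):
        outcome_id = name.split(":", 1)[1]
        hits = [
            e
            for e in b.effects
            if e.outcome_id == outcome_id and e.comparison == comparison
        ]
        if not hits:
            raise KeyError(f"no effect '{outcome_id}' for comparison {comparison.value}")
        for e in hits:
            e.point = value
            e.ci_low = min(e.ci_low, value)
            e.ci_high = max(e.ci_high, value)
        return b
    if name == "discount_rate":
        b.econ_params.discount_rate = value
    elif name == "growth_rate":
        b.econ_params.growth_rate = value
    elif name == "vsl":
        b.econ_params.vsl_override = value
    elif name == "vsly":
        b.econ_params.vsly_override = value
    elif name == "cost_scale":
        for c in b.unit_costs:
            c.component_costs = {k: v * value for k, v in c.component_costs.items()}
    else:
        raise KeyError(f"unresolvable scenario parameter: {name}")
    return b


def _bcr_for(bundle: StudyBundle, comparison: Comparison) -> float:
    for r in run_full_analysis(bundle):
        if r.comparison == comparison:
            return r.bcr
    raise KeyError(f"comparison {comparison.value} absent from bundle")


def one_way(
    bundle: StudyBundle,
    params: Sequence[ScenarioParam],
    comparison: Comparison,
) -> list[TornadoRow]:
    """Evaluate each scenario parameter at its low/base/best value.

    Every row's base BCR is required to be bit-identical to the base-case
    BCR (applying the base value must reconstruct the base-case bundle);
    a mismatch means the supplied base value disagrees with the bundle.
    """
    base_bcr = _bcr_for(bundle, comparison)
    rows: list[TornadoRow] = []
    for p in params:
        bcrs = {
            which: _bcr_for(_apply(bundle, p.name, value, comparison), comparison)
            for which, value in (("low", p.low), ("base", p.base), ("best", p.best))
        }
        if bcrs["base"] != base_bcr:
            raise ValueError(
                f"{p.name}: base value {p.base} does not reproduce the "
                f"base-case BCR ({bcrs['base']} != {base_bcr})"
            )
        lo, hi = bcrs["low"], bcrs["best"]
        if lo > hi:  # orient so the low case worsens the BCR
            lo, hi = hi, lo
        rows.append(
            TornadoRow(
                name=p.name, bcr_low=lo, bcr_base=base_bcr, bcr_best=hi, range=hi - lo
            )
        )
    rows.sort(key=lambda r: r.name)  # stable alphabetical tie-break
    rows.sort(key=lambda r: -r.range)
    return rows


def default_scenarios(
    bundle: StudyBundle, comparison: Comparison
) -> list[ScenarioParam]:
    """Scenario set mirroring the published one-way analysis: every effect
    size at its CI endpoints, discount rate 3/5/7%, growth rate, VSL, VSLY
    and the delivery-cost scale. VSL/VSLY/growth/cost ranges are placeholders
    (the study's exact low/best values were not published)."""
    from .benefit_valuation import compute_vsl, compute_vsly

    params: list[ScenarioParam] = []
    for e in bundle.effects_for(comparison):
        if e.ci_low == e.ci_high == e.point:
            continue
        # benefit is increasing in the stored effect for both metrics
        params.append(
            ScenarioParam(
                name=f"effect:{e.outcome_id}", low=e.ci_low, base=e.point, best=e.ci_high
            )
        )
    ep = bundle.econ_params
    vsl = compute_vsl(ep)
    vsly = compute_vsly(vsl, ep)
    params += [
        ScenarioParam(name="discount_rate", low=0.07, base=ep.discount_rate, best=ep.discount_rate),
        ScenarioParam(name="growth_rate", low=max(ep.growth_rate - 0.02, 0.0), base=ep.growth_rate, best=ep.growth_rate + 0.02),
        ScenarioParam(name="vsl", low=0.5 * vsl, base=vsl, best=1.5 * vsl),
        ScenarioParam(name="vsly", low=0.5 * vsly, base=vsly, best=1.5 * vsly),
        ScenarioParam(name="cost_scale", low=2.0, base=1.0, best=0.5),
    ]
    return params


def tornado_export(rows: Sequence[TornadoRow], path: str | Path) -> None:
    """Write tornado rows as TSV (name, bcr_low, bcr_base, bcr_best, range),
    in computed order."""
    if not rows:
        raise ValueError("no tornado rows to export")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tbcr_low\tbcr_base\tbcr_best\trange\n")
        for r in rows:
            fh.write(
                f"{r.name}\t{r.bcr_low:.6f}\t{r.bcr_base:.6f}"
                f"\t{r.bcr_best:.6f}\t{r.range:.6f}\n"
            )
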