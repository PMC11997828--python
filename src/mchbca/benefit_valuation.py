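"""Monetization of trial effect sizes via mortality, morbidity and
productivity channels.

Mortality: a risk reduction of ARR percentage points averts ARR/100 deaths
per dyad, each valued at one VSL (= 100 x GNI per capita PPP, income
elasticity 1, no age adjustment). Morbidity: the change in years lived with
disability, ARR/100 x disability weight x persistence T1, valued at one VSLY
(= VSL/35) per DALY. Productivity: the effect times the fraction f of
discounted lifetime earnings it shifts, deflated by the overlap weight w to
avoid double counting across pathways (birth weight, height, cognition,
nutrition, schooling).

Deaths and short-lived maternal conditions fall within the first two years,
so mortality and morbidity values are undiscounted by default;
``EconParams.discount_mortality`` / ``discount_morbidity`` switch on
discounting for scenario work. Earnings streams are always discounted.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    Channel,
    Comparison,
    EconParams,
    EffectEstimate,
    Metric,
    MonetaryBenefit,
    OutcomeSpec,
    ParticipantFlow,
)

logger = logging.getLogger(__name__)

HEALTHCARE_SAVINGS_ID = "healthcare_savings"


def compute_vsl(
    params: EconParams, reference: Optional[tuple[float, float]] = None
) -> float:
    """Value of statistical life for the study setting.

    Default: ``gni_pc_ppp * vsl_ratio``. With a ``(vsl_ref, income_ref)``
    benchmark pair, the VSL is transferred as
    ``vsl_ref * (gni / income_ref) ** income_elasticity``; at elasticity 1
    and ratio-consistent benchmarks the two coincide.
    """
    if params.gni_pc_ppp <= 0:
        raise ValueError("gni_pc_ppp must be > 0")
    if reference is not None:
        vsl_ref, income_ref = reference
        if income_ref <= 0:
            raise ValueError("reference income must be > 0")
        return vsl_ref * (params.gni_pc_ppp / income_ref) ** params.income_elasticity
    return params.gni_pc_ppp * params.vsl_ratio


def compute_vsly(vsl: float, params: EconParams) -> float:
    """Value of a statistical life year: VSL over the productive lifespan."""
    if vsl <= 0:
        raise ValueError("vsl must be > 0")
    return vsl / params.vsly_divisor


def resolve_vsl_vsly(params: EconParams) -> tuple[float, float]:
    """Base-case VSL/VSLY, honouring sensitivity-scenario overrides."""
    vsl = params.vsl_override if params.vsl_override is not None else compute_vsl(params)
    vsly = (
        params.vsly_override
        if params.vsly_override is not None
        else compute_vsly(vsl, params)
    )
    return vsl, vsly


def discounted_stream(
    per_period_value: float, population: float, horizon: int, rate: float
) -> float:
    """Present value of a constant per-period flow over years 0..horizon:
    ``sum_t P * B * (1+r)^-t``, equal to the geometric closed form for r>0."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t = np.arange(int(horizon) + 1, dtype=float)
    return float(population * per_period_value * np.sum((1.0 + rate) ** (-t)))


def persistence_factor(years: float, rate: float) -> float:
    """Discounted years of persistence, allowing fractional horizons.

    Whole years are discounted annually; the fractional remainder accrues at
    the following year's discount factor. At ``rate`` 0 this is ``years``
    itself, i.e. the YLD duration.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    full = int(np.floor(years))
    frac = years - full
    t = np.arange(full, dtype=float)
    return float(np.sum((1.0 + rate) ** (-t)) + frac * (1.0 + rate) ** (-float(full)))


def _oriented_effect(effect: EffectEstimate) -> float:
    """Effect magnitude oriented so a beneficial effect is positive.

    ARRs are stored as reductions (positive = good) in percentage points and
    are converted to fractions here; mean differences pass through in the
    outcome's own unit.
    """
    if effect.metric is Metric.ARR_percent:
        return effect.point / 100.0
    return effect.point


def mortality_benefit(
    effect: EffectEstimate, vsl: float, params: EconParams
) -> MonetaryBenefit:
    """Per-dyad value of averted stillbirths and deaths in the first two years."""
    if effect.metric is not Metric.ARR_percent:
        raise ValueError(
            f"{effect.outcome_id}: mortality valuation requires an ARR_percent effect"
        )
    value = _oriented_effect(effect) * vsl
    if params.discount_mortality:
        value *= (1.0 + params.discount_rate) ** (-1.0)  # midpoint of the 0-2y window
    return MonetaryBenefit(
        outcome_id=effect.outcome_id, comparison=effect.comparison, value=value
    )


def morbidity_benefit(
    effect: EffectEstimate, spec: OutcomeSpec, vsly: float, params: EconParams
) -> MonetaryBenefit:
    """Per-dyad value of averted years lived with disability.

    Averted YLD = ARR/100 x disability weight x persistence T1; one DALY is
    valued at one VSLY. Persistence is undiscounted unless
    ``params.discount_morbidity`` is set.
    """
    if spec.disability_weight is None or spec.persistence_years is None:
        raise ValueError(
            f"{effect.outcome_id}: missing disability_weight or persistence_years"
        )
    if effect.metric is not Metric.ARR_percent:
        raise ValueError(
            f"{effect.outcome_id}: morbidity valuation requires an ARR_percent effect"
        )
    rate = params.discount_rate if params.discount_morbidity else 0.0
    value = (
        _oriented_effect(effect)
        * spec.disability_weight
        * vsly
        * persistence_factor(spec.persistence_years, rate)
    )
    return MonetaryBenefit(
        outcome_id=effect.outcome_id, comparison=effect.comparison, value=value
    )


def earnings_present_value(params: EconParams, baseline_earnings: float) -> float:
    """PV of lifetime earnings: ``sum_{t=a}^{a+W-1} y0 (1+g)^t (1+r)^-t``
    over ``working_years`` W from ``earnings_start_age`` a. When g = r the
    growth and discount factors cancel and the PV collapses to ``W * y0``."""
    a = params.earnings_start_age
    t = a + np.arange(params.working_years, dtype=float)
    return float(
        baseline_earnings
        * np.sum((1.0 + params.growth_rate) ** t * (1.0 + params.discount_rate) ** (-t))
    )


def productivity_benefit(
    effect: EffectEstimate,
    spec: OutcomeSpec,
    params: EconParams,
    baseline_earnings: Optional[float] = None,
) -> MonetaryBenefit:
    """Per-dyad value of lifetime earnings gained through one pathway.

    value = w x f x effect x PV(earnings), with the overlap weight w
    deflating pathways that act through shared mechanisms.
    """
    if spec.productivity_fraction is None:
        raise ValueError(f"{effect.outcome_id}: missing productivity_fraction")
    y0 = (
        baseline_earnings
        if baseline_earnings is not None
        else (params.baseline_earnings or params.gni_pc_ppp)
    )
    if y0 is None or y0 <= 0:
        raise ValueError(f"{effect.outcome_id}: missing baseline earnings")
    value = (
        params.overlap_weight
        * spec.productivity_fraction
        * _oriented_effect(effect)
        * earnings_present_value(params, y0)
    )
    return MonetaryBenefit(
        outcome_id=effect.outcome_id, comparison=effect.comparison, value=value
    )


def value_all_benefits(
    effects: Sequence[EffectEstimate],
    specs: Sequence[OutcomeSpec],
    params: EconParams,
    flow: Optional[ParticipantFlow] = None,
) -> tuple[list[MonetaryBenefit], dict[Comparison, float]]:
    """Route every effect to its valuation channel and total per comparison.

    Returns per-dyad monetary benefits (one per effect, plus an optional
    healthcare-savings line per comparison when configured) and the per-dyad
    total for each comparison present. Effects whose outcome lacks a spec
    raise; specs without disability weights never reach valuation by
    construction (such outcomes are excluded upstream, with a warning, as in
    the source analysis). ``flow`` is accepted for population-level scaling
    by callers and does not alter per-dyad values.
    """
    spec_map = {s.outcome_id: s for s in specs}
    unrouted = sorted({e.outcome_id for e in effects} - set(spec_map))
    if unrouted:
        raise KeyError(f"no OutcomeSpec for outcomes: {unrouted}")
    vsl, vsly = resolve_vsl_vsly(params)

    benefits: list[MonetaryBenefit] = []
    comparisons: list[Comparison] = []
    for effect in effects:
        spec = spec_map[effect.outcome_id]
        if spec.channel is Channel.mortality:
            b = mortality_benefit(effect, vsl, params)
        elif spec.channel is Channel.morbidity:
            b = morbidity_benefit(effect, spec, vsly, params)
        else:
            b = productivity_benefit(effect, spec, params)
        benefits.append(b)
        if effect.comparison not in comparisons:
            comparisons.append(effect.comparison)

    if params.healthcare_savings_per_dyad:
        for comp in comparisons:
            benefits.append(
                MonetaryBenefit(
                    outcome_id=HEALTHCARE_SAVINGS_ID,
                    comparison=comp,
                    value=params.healthcare_savings_per_dyad,
                )
            )

    totals = {
        comp: sum(b.value for b in benefits if b.comparison == comp)
        for comp in comparisons
    }
    return benefits, totals
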