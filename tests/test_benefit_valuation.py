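"""Monetization channels: VSL/VSLY, discounted streams, per-channel values."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mchbca import (
    Comparison,
    EconParams,
    EffectEstimate,
    OutcomeSpec,
    compute_vsl,
    compute_vsly,
    discounted_stream,
    earnings_present_value,
    morbidity_benefit,
    mortality_benefit,
    persistence_factor,
    productivity_benefit,
    value_all_benefits,
)


def _arr_effect(point, outcome_id="x", period="childhood"):
    span = max(abs(point), 1.0)
    return EffectEstimate(
        outcome_id=outcome_id,
        period=period,
        comparison=Comparison.B_vs_control,
        metric="ARR_percent",
        point=point,
        ci_low=point - span,
        ci_high=point + span,
    )


def _md_effect(point, outcome_id="x"):
    return EffectEstimate(
        outcome_id=outcome_id,
        period="childhood",
        comparison=Comparison.B_vs_control,
        metric="mean_difference",
        point=point,
        ci_low=point - 1.0,
        ci_high=point + 1.0,
    )


class TestVslVsly:
    def test_default_formula(self):
        assert compute_vsl(EconParams(gni_pc_ppp=7000.0)) == 700000.0

    def test_identity_case(self):
        assert compute_vsl(EconParams(gni_pc_ppp=1.0, vsl_ratio=1.0)) == 1.0

    def test_elasticity_one_transfer_matches_ratio(self):
        """At elasticity 1 and a ratio-consistent benchmark, transferring a
        reference VSL equals the direct GNI x ratio formula."""
        params = EconParams(gni_pc_ppp=7130.0, vsl_ratio=100.0, income_elasticity=1.0)
        income_ref = 64000.0
        vsl_ref = 100.0 * income_ref
        assert compute_vsl(params, reference=(vsl_ref, income_ref)) == pytest.approx(
            compute_vsl(params)
        )

    def test_bad_reference_income(self):
        with pytest.raises(ValueError):
            compute_vsl(EconParams(gni_pc_ppp=7130.0), reference=(1e6, 0.0))

    @pytest.mark.parametrize(
        "vsl, divisor, expected", [(700000.0, 35.0, 20000.0), (35.0, 35.0, 1.0), (7.0, 1.0, 7.0)]
    )
    def test_vsly(self, vsl, divisor, expected):
        params = EconParams(gni_pc_ppp=1.0, vsly_divisor=divisor)
        assert compute_vsly(vsl, params) == expected

    def test_vsly_requires_positive_vsl(self):
        with pytest.raises(ValueError):
            compute_vsly(0.0, EconParams(gni_pc_ppp=1.0))


class TestDiscountedStream:
    def test_undiscounted_sum(self):
        assert discounted_stream(100.0, 1, 2, 0.0) == pytest.approx(300.0)

    def test_two_year_stream_at_3pct(self):
        # 100 + 100/1.03 computed term by term
        assert discounted_stream(100.0, 1, 1, 0.03) == pytest.approx(197.0874, abs=1e-4)

    def test_horizon_zero(self):
        for r in (0.0, 0.03, 0.15):
            assert discounted_stream(55.0, 3, 0, r) == pytest.approx(165.0)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            discounted_stream(1.0, 1, -1, 0.03)

    @settings(max_examples=200, derandomize=True)
    @given(
        rate=st.floats(1e-6, 0.2),
        horizon=st.integers(0, 200),
        value=st.floats(0.01, 1e6),
    )
    def test_matches_geometric_closed_form(self, rate, horizon, value):
        loop = discounted_stream(value, 1, horizon, rate)
        # numerically stable geometric closed form: 1 - q^(T+1) over 1 - q
        log_q = -np.log1p(rate)
        closed = value * np.expm1((horizon + 1) * log_q) / np.expm1(log_q)
        assert loop == pytest.approx(closed, rel=1e-9)


class TestPersistenceFactor:
    def test_undiscounted_equals_duration(self):
        assert persistence_factor(1.5, 0.0) == 1.5
        assert persistence_factor(2.0, 0.0) == 2.0

    def test_fractional_year_discounted(self):
        # one full year + half a year at the next year's discount factor
        assert persistence_factor(1.5, 0.03) == pytest.approx(1.0 + 0.5 / 1.03)

    def test_integer_horizon_matches_stream(self):
        assert persistence_factor(3.0, 0.05) == pytest.approx(
            discounted_stream(1.0, 1, 2, 0.05)
        )


class TestMortality:
    def test_linear_scaling(self):
        params = EconParams(gni_pc_ppp=1000.0)
        b = mortality_benefit(_arr_effect(1.0), 100000.0, params)
        assert b.value == pytest.approx(1000.0)

    def test_zero_effect(self):
        params = EconParams(gni_pc_ppp=1000.0)
        assert mortality_benefit(_arr_effect(0.0), 100000.0, params).value == 0.0

    def test_harm_is_negative(self):
        params = EconParams(gni_pc_ppp=1000.0)
        assert mortality_benefit(_arr_effect(-1.0), 100000.0, params).value < 0

    def test_md_metric_rejected(self):
        with pytest.raises(ValueError, match="ARR_percent"):
            mortality_benefit(_md_effect(0.1), 1e5, EconParams(gni_pc_ppp=1000.0))

    def test_optional_discounting_shrinks_value(self):
        on = EconParams(gni_pc_ppp=1000.0, discount_mortality=True)
        off = EconParams(gni_pc_ppp=1000.0)
        v_on = mortality_benefit(_arr_effect(2.0), 1e5, on).value
        v_off = mortality_benefit(_arr_effect(2.0), 1e5, off).value
        assert v_on == pytest.approx(v_off / 1.03)


class TestMorbidity:
    def _spec(self, dw, t1):
        return OutcomeSpec(
            outcome_id="x",
            beneficiary="woman",
            channel="morbidity",
            disability_weight=dw,
            persistence_years=t1,
        )

    def test_single_undiscounted_year(self):
        params = EconParams(gni_pc_ppp=1.0)
        b = morbidity_benefit(_arr_effect(10.0), self._spec(0.05, 1.0), 1000.0, params)
        assert b.value == pytest.approx(5.0)

    def test_zero_disability_weight(self):
        params = EconParams(gni_pc_ppp=1.0)
        b = morbidity_benefit(_arr_effect(10.0), self._spec(0.0, 1.0), 1000.0, params)
        assert b.value == 0.0

    def test_two_year_discounted_stream(self):
        """ARR 10%, DW 0.2, 2 years of 1000/yr at 3%: 0.1*0.2*(1000+1000/1.03)."""
        params = EconParams(gni_pc_ppp=1.0, discount_morbidity=True)
        b = morbidity_benefit(_arr_effect(10.0), self._spec(0.2, 2.0), 1000.0, params)
        assert b.value == pytest.approx(39.417, abs=1e-3)

    def test_undiscounted_default_uses_duration(self):
        params = EconParams(gni_pc_ppp=1.0)
        b = morbidity_benefit(_arr_effect(10.0), self._spec(0.2, 2.0), 1000.0, params)
        assert b.value == pytest.approx(0.1 * 0.2 * 2000.0)

    def test_missing_weight_rejected(self):
        spec = OutcomeSpec(outcome_id="x", beneficiary="child", channel="mortality")
        with pytest.raises(ValueError, match="disability_weight"):
            morbidity_benefit(_arr_effect(1.0), spec, 1000.0, EconParams(gni_pc_ppp=1.0))


class TestProductivity:
    def _spec(self, f):
        return OutcomeSpec(
            outcome_id="x",
            beneficiary="child",
            channel="productivity",
            productivity_fraction=f,
        )

    def test_zero_fraction_or_weight(self):
        params = EconParams(gni_pc_ppp=1000.0)
        assert productivity_benefit(_arr_effect(5.0), self._spec(0.0), params).value == 0.0

    def test_growth_discount_cancellation(self):
        """g = r collapses the earnings stream to working_years x y0."""
        params = EconParams(
            gni_pc_ppp=1000.0, growth_rate=0.03, discount_rate=0.03, working_years=35
        )
        assert earnings_present_value(params, 1000.0) == pytest.approx(35000.0)

    def test_hand_computed_example(self):
        """ARR 5%, f 0.1, w 0.6, y0 1000, 2 working years, g = r = 0 -> 6.0."""
        params = EconParams(
            gni_pc_ppp=1000.0,
            growth_rate=0.0,
            discount_rate=0.0,
            earnings_start_age=0.0,
            working_years=2,
            overlap_weight=0.6,
        )
        b = productivity_benefit(
            _arr_effect(5.0), self._spec(0.1), params, baseline_earnings=1000.0
        )
        assert b.value == pytest.approx(0.05 * 0.1 * 0.6 * 2000.0)

    def test_mean_difference_uses_outcome_unit(self):
        params = EconParams(
            gni_pc_ppp=1000.0,
            growth_rate=0.0,
            discount_rate=0.0,
            earnings_start_age=0.0,
            working_years=1,
            overlap_weight=1.0,
        )
        b = productivity_benefit(_md_effect(0.5), self._spec(0.2), params)
        assert b.value == pytest.approx(0.5 * 0.2 * 1000.0)

    def test_missing_fraction_rejected(self):
        spec = OutcomeSpec(outcome_id="x", beneficiary="child", channel="mortality")
        with pytest.raises(ValueError, match="productivity_fraction"):
            productivity_benefit(_arr_effect(1.0), spec, EconParams(gni_pc_ppp=1.0))


class TestValueAll:
    def test_totals_equal_breakdown_sum_exactly(self, bundle):
        benefits, totals = value_all_benefits(
            bundle.effects, bundle.outcome_specs, bundle.econ_params
        )
        for comp, total in totals.items():
            assert total == sum(b.value for b in benefits if b.comparison == comp)

    def test_unrouted_outcome_listed(self, bundle):
        stray = _arr_effect(1.0, outcome_id="mystery_outcome")
        with pytest.raises(KeyError, match="mystery_outcome"):
            value_all_benefits(
                bundle.effects + [stray], bundle.outcome_specs, bundle.econ_params
            )

    def test_healthcare_savings_line(self, bundle):
        params = bundle.econ_params.model_copy(
            update={"healthcare_savings_per_dyad": 100.0}
        )
        _, totals = value_all_benefits(bundle.effects, bundle.outcome_specs, params)
        _, base = value_all_benefits(
            bundle.effects, bundle.outcome_specs, bundle.econ_params
        )
        for comp in totals:
            assert totals[comp] == pytest.approx(base[comp] + 100.0)

    def test_monotone_nonincreasing_in_discount_rate(self, bundle):
        """For positive-valued effects, raising r cannot raise the benefit."""
        params = bundle.econ_params.model_copy(
            update={"discount_morbidity": True, "discount_mortality": True}
        )
        positive = [e for e in bundle.effects if e.point > 0]
        totals = []
        for r in (0.03, 0.05, 0.07):
            p = params.model_copy(update={"discount_rate": r, "growth_rate": 0.0})
            _, t = value_all_benefits(positive, bundle.outcome_specs, p)
            totals.append(sum(t.values()))
        assert totals[0] >= totals[1] >= totals[2]

    def test_linearity_in_effect_and_vsl(self, bundle):
        """Doubling every effect, or the VSL, doubles the matching benefits."""
        _, base = value_all_benefits(
            bundle.effects, bundle.outcome_specs, bundle.econ_params
        )
        doubled_effects = [
            e.model_copy(
                update={
                    "point": 2 * e.point,
                    "ci_low": min(2 * e.ci_low, 2 * e.point),
                    "ci_high": max(2 * e.ci_high, 2 * e.point),
                }
            )
            for e in bundle.effects
        ]
        _, doubled = value_all_benefits(
            doubled_effects, bundle.outcome_specs, bundle.econ_params
        )
        for comp in base:
            assert doubled[comp] == pytest.approx(2 * base[comp], rel=1e-12)

        vsl2 = bundle.econ_params.model_copy(
            update={"vsl_override": 2 * compute_vsl(bundle.econ_params)}
        )
        mortality_only = [e for e in bundle.effects if e.outcome_id == "mortality"]
        _, b1 = value_all_benefits(
            mortality_only, bundle.outcome_specs, bundle.econ_params
        )
        _, b2 = value_all_benefits(mortality_only, bundle.outcome_specs, vsl2)
        for comp in b1:
            assert b2[comp] == pytest.approx(2 * b1[comp], rel=1e-12)
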