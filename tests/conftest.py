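"""Shared fixtures: the packaged study bundle and small synthetic worlds."""

from __future__ import annotations

import pytest

from mchbca import (
    BinaryOutcome,
    Comparison,
    ContinuousOutcome,
    EconParams,
    OutcomeSpec,
    Phase,
    PhaseUnitCost,
    SyntheticConfig,
    load_packaged_study,
)

#: Published headline values the packaged fixture is calibrated to reproduce.
PRINTED = {
    "benefits": {"B": 8805.3, "C": 28843.9, "A": 16182.0},
    "costs": {"B": 1441.1, "C": 2926.8, "A": 4367.9},
    "bcr": {"B": 6.1, "C": 9.9, "A": 3.7},
    "nmb": {"B": 7364.2, "C": 25917.1, "A": 11814.1},
}

COMP = {
    "B": Comparison.B_vs_control,
    "C": Comparison.C_vs_control,
    "A": Comparison.A_vs_control,
}


@pytest.fixture(scope="session")
def bundle():
    return load_packaged_study()


@pytest.fixture()
def mutable_bundle(bundle):
    return bundle.model_copy(deep=True)


@pytest.fixture(scope="session")
def results(bundle):
    from mchbca import run_full_analysis

    return {r.comparison: r for r in run_full_analysis(bundle)}


def make_unit_costs(pre=500.0, preg=1000.0, ec=1800.0):
    """Single-component phase costs with the given totals."""
    return [
        PhaseUnitCost(
            phase=Phase.preconception,
            component_costs={"human_resource": pre},
            duration_months=11,
        ),
        PhaseUnitCost(
            phase=Phase.pregnancy,
            component_costs={"human_resource": preg},
            duration_months=7,
        ),
        PhaseUnitCost(
            phase=Phase.early_childhood,
            component_costs={"human_resource": ec},
            duration_months=24,
        ),
    ]


def recovery_world(n_women: int, seed: int):
    """A synthetic world sized so end-to-end BCR recovery at n = 50 000 has
    a delta-method Monte-Carlo error comfortably inside 5 percent.

    Benefits are dominated by a high-prevalence, large-effect maternal
    morbidity outcome (women contribute ~n/2.5 per arm); the child outcomes
    (estimated on ~n/11 dyads per arm) carry deliberately small shares so
    their noise cannot swamp the ratio.
    """
    econ = EconParams(gni_pc_ppp=7000.0, discount_rate=0.03, growth_rate=0.03)
    config = SyntheticConfig(
        n_women=n_women,
        binary_outcomes={
            "maternal_infection": BinaryOutcome(
                control_risk=0.45,
                arr_percent={
                    Comparison.B_vs_control: 30.0,
                    Comparison.C_vs_control: 25.0,
                    Comparison.A_vs_control: 35.0,
                },
                period="preconception",
            ),
            "maternal_anaemia": BinaryOutcome(
                control_risk=0.30,
                arr_percent={
                    Comparison.B_vs_control: 15.0,
                    Comparison.C_vs_control: 10.0,
                    Comparison.A_vs_control: 20.0,
                },
                period="preconception",
            ),
            "child_stunting": BinaryOutcome(
                control_risk=0.35,
                arr_percent={
                    Comparison.B_vs_control: 5.0,
                    Comparison.C_vs_control: 8.0,
                    Comparison.A_vs_control: 10.0,
                },
                period="childhood",
            ),
        },
        continuous_outcomes={
            "child_cognition": ContinuousOutcome(
                control_mean=0.0,
                sd=1.0,
                md={
                    Comparison.B_vs_control: 0.10,
                    Comparison.C_vs_control: 0.20,
                    Comparison.A_vs_control: 0.25,
                },
                period="childhood",
            ),
        },
        unit_costs=make_unit_costs(),
        seed=seed,
    )
    specs = [
        OutcomeSpec(
            outcome_id="maternal_infection",
            beneficiary="woman",
            channel="morbidity",
            disability_weight=0.30,
            persistence_years=6.0,
        ),
        OutcomeSpec(
            outcome_id="maternal_anaemia",
            beneficiary="woman",
            channel="morbidity",
            disability_weight=0.10,
            persistence_years=2.0,
        ),
        OutcomeSpec(
            outcome_id="child_stunting",
            beneficiary="child",
            channel="productivity",
            productivity_fraction=0.06,
        ),
        OutcomeSpec(
            outcome_id="child_cognition",
            beneficiary="child",
            channel="productivity",
            productivity_fraction=0.025,
        ),
    ]
    return config, econ, specs
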