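import pytest
from hypothesis import HealthCheck, settings

from hipimpact import (
    FactorSpec,
    MedicationSpec,
    PerSex,
    Scenario,
    StratumRecord,
    load_romania_fixture,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def romania() -> Scenario:
    return load_romania_fixture()


def make_single_stratum_scenario(
    factors=(),
    medications=(),
    observed_ey: float = 700.0,
    pop: float = 1_000_000.0,
    observed_by: float = 500.0,
) -> Scenario:
    """A minimal one-stratum scenario (baseline rate 5 per 10,000 by default)."""
    return Scenario(
        baseline_year=2008,
        end_year=2018,
        strata=[
            StratumRecord(
                sex="women",
                pop_by=pop,
                pop_ey=pop,
                observed_by=observed_by,
                observed_ey=observed_ey,
            )
        ],
        factors=list(factors),
        medications=list(medications),
    )


def make_monotone_toy() -> Scenario:
    """One stratum, two harmful factors with rising prevalence, one medication.

    Every parameter enters the modeled excess monotonically: prevalences are
    separated enough that BY/EY bound boxes cannot overlap under the +/- 20%
    rule, and relative risks stay in (1, 2] at both bounds, where the PARF
    difference is increasing in RR.
    """
    def ps(v: float) -> PerSex:
        return PerSex(by_sex={"women": v})

    factors = [
        FactorSpec(
            name="exposure_a",
            category="risk_factor",
            prevalence_by=ps(0.10),
            prevalence_ey=ps(0.50),
            relative_risk=ps(1.30),
        ),
        FactorSpec(
            name="exposure_b",
            category="drug_side_effect",
            prevalence_by=ps(0.05),
            prevalence_ey=ps(0.40),
            relative_risk=ps(1.50),
        ),
    ]
    medications = [
        MedicationSpec(
            name="med_a",
            users_by=ps(2_000.0),
            users_ey=ps(5_000.0),
            rrr=0.5,
            osteo_rr=ps(4.0),
        )
    ]
    return make_single_stratum_scenario(
        factors=factors, medications=medications, observed_ey=800.0
    )
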