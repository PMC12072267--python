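"""Synthetic scenarios with known ground truth, and the packaged fixture.

The generator builds two-stratum scenarios whose end-year observed counts are
constructed by the same forward equations the attribution engine inverts:
per-factor contributions NE * (PARF(EY) - PARF(BY)), the overlap adjustment
applied to the risk and drug subtotals, and the medication term. Because the
medication term uses the end-year population rate — which itself depends on
the end-year observed count — the construction solves the resulting linear
fixed point in closed form:

    observed = (NE + adjusted factor contributions) / (1 + k),
    k = sum over medication groups of users_EY * rrr * osteo_RR / pop_EY

so that noise-free scenarios are recovered exactly by the engine (this tests
plumbing and sign conventions, not the epidemiological validity of the model —
ground truth and engine share the same equations by design).

Study-condition defaults: prevalences uniform in [0.02, 0.8] with the end-year
value shifted by a uniform delta in [-0.15, 0.15] (clipped to [0, 1]);
relative risks log-uniform in [0.5, 2.0]; baseline rates uniform in [2, 12]
per 10,000. All randomness flows through one numpy Generator seeded
explicitly; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .attribution import (
    RISK_CATEGORIES,
    AdjustmentInput,
    adjustment_factor,
    decompose,
    parf,
)
from .expectation import compute_expectation, expected_count, incidence_rate
from .scenario import (
    FactorSpec,
    MedicationSpec,
    PerSex,
    Scenario,
    StratumRecord,
    scenario_from_dict,
)

_FIXTURE = "romania_2008_2018.yaml"


def load_romania_fixture() -> Scenario:
    """The packaged Romania 2008-2018 scenario (two strata, five risk or
    preventive factors, four drug classes, one medication group)."""
    import yaml

    text = resources.files("hipimpact.data").joinpath(_FIXTURE).read_text()
    return scenario_from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated scenario plus the contributions injected into it."""

    scenario: Scenario
    injected_contributions: dict[str, dict[str, float]]  # factor -> sex -> nx
    injected_med: dict[str, float]  # sex -> nx (all medication groups summed)
    implied_observed_ey: dict[str, float]  # sex -> noise-free observed count
    seed: int


def generate_scenario(
    seed: int,
    n_factors: int = 3,
    n_meds: int = 1,
    pop_scale: float = 5_000_000,
) -> SyntheticTruth:
    """Generate a two-stratum scenario with known injected contributions.

    Deterministic given ``seed``. Every third factor is a drug class so both
    component groups are exercised when ``n_factors`` >= 3.
    """
    if n_factors < 0 or n_meds < 0:
        raise ValueError("n_factors and n_meds must be >= 0")
    if pop_scale <= 0:
        raise ValueError("pop_scale must be > 0")
    rng = np.random.default_rng(seed)
    sexes = ["women", "men"]

    strata = []
    for sex in sexes:
        pop_by = float(np.floor(pop_scale * rng.uniform(0.9, 1.1)))
        pop_ey = float(np.floor(pop_by * rng.uniform(0.9, 1.1)))
        rate_by = rng.uniform(2.0, 12.0)  # per 10,000
        observed_by = expected_count(rate_by, pop_by)
        strata.append(
            StratumRecord(
                sex=sex,
                pop_by=pop_by,
                pop_ey=pop_ey,
                observed_by=float(observed_by),
                observed_ey=0.0,  # placeholder, set from the forward model
            )
        )

    factors = []
    for i in range(n_factors):
        category = "drug_side_effect" if i % 3 == 2 else (
            "risk_factor" if i % 3 == 0 else "preventive"
        )
        p_by, p_ey, rr = {}, {}, {}
        for sex in sexes:
            p = rng.uniform(0.02, 0.8)
            delta = rng.uniform(-0.15, 0.15)
            p_by[sex] = p
            p_ey[sex] = float(np.clip(p + delta, 0.0, 1.0))
            rr[sex] = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        factors.append(
            FactorSpec(
                name=f"factor_{i:02d}",
                category=category,
                prevalence_by=PerSex(by_sex=p_by),
                prevalence_ey=PerSex(by_sex=p_ey),
                relative_risk=PerSex(by_sex=rr),
            )
        )

    medications = []
    for j in range(n_meds):
        medications.append(
            MedicationSpec(
                name=f"medication_{j:02d}",
                users_by=PerSex(
                    by_sex={s: float(rng.integers(1_000, 50_000)) for s in sexes}
                ),
                users_ey=PerSex(
                    by_sex={s: float(rng.integers(1_000, 50_000)) for s in sexes}
                ),
                rrr=float(rng.uniform(0.2, 0.8)),
                osteo_rr=PerSex(
                    by_sex={s: float(rng.uniform(2.0, 8.0)) for s in sexes}
                ),
            )
        )

    scenario = Scenario(
        baseline_year=2008,
        end_year=2018,
        strata=strata,
        factors=factors,
        medications=medications,
    )

    # Forward model: expected counts, adjusted factor sums, medication fixed
    # point — exactly the quantities the engine recomputes.
    ne = {
        s.sex: expected_count(incidence_rate(s.observed_by, s.pop_by), s.pop_ey)
        for s in scenario.strata
    }
    injected: dict[str, dict[str, float]] = {}
    for f in scenario.factors:
        injected[f.name] = {
            sex: ne[sex]
            * (
                parf(f.prevalence_ey[sex], f.relative_risk[sex])
                - parf(f.prevalence_by[sex], f.relative_risk[sex])
            )
            for sex in sexes
        }
    af = 1.0
    if scenario.factors:
        total_ne = sum(ne.values())
        mags = [
            sum(abs(injected[f.name][sex]) for sex in sexes) / total_ne
            for f in scenario.factors
        ]
        af = adjustment_factor(
            AdjustmentInput(risk_magnitudes=mags, interpretation="delta_parf")
        ).af

    injected_med: dict[str, float] = {}
    implied: dict[str, float] = {}
    for s in scenario.strata:
        risk_s = af * sum(injected[f.name][s.sex] for f in scenario.factors)
        k = sum(
            m.users_ey[s.sex] * m.rrr * m.osteo_rr[s.sex] / s.pop_ey
            for m in scenario.medications
        )
        observed = (ne[s.sex] + risk_s) / (1.0 + k)
        if observed < 0:
            raise ValueError(
                "generated contributions drive the observed count negative; "
                "use fewer factors or a larger population scale"
            )
        injected_med[s.sex] = -k * observed
        implied[s.sex] = observed
        s.observed_ey = observed

    return SyntheticTruth(
        scenario=scenario,
        injected_contributions=injected,
        injected_med=injected_med,
        implied_observed_ey=implied,
        seed=seed,
    )


def add_poisson_noise(truth: SyntheticTruth, seed: int) -> Scenario:
    """Replace the noise-free end-year counts with Poisson draws.

    Per stratum, observed_EY ~ Poisson(implied_observed_EY); deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    scenario = truth.scenario.model_copy(deep=True)
    for s in scenario.strata:
        mean = truth.implied_observed_ey[s.sex]
        s.observed_ey = float(rng.poisson(mean))
    return scenario


def recovered_percent(truth: SyntheticTruth) -> float:
    """Percent explained when the engine is run on a truth's scenario."""
    return decompose(truth.scenario, track="equations").percent_explained


__all__ = [
    "SyntheticTruth",
    "load_romania_fixture",
    "generate_scenario",
    "add_poisson_noise",
    "recovered_percent",
    "compute_expectation",
]
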