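"""Attribution engine: PARF-based contributions, medication component,
overlap adjustment, and aggregation into the modeled excess.

For a binary exposure with prevalence P and relative risk RR, the population
attributable risk fraction is

    PARF = P (RR - 1) / (P (RR - 1) + 1)

positive for harmful exposures (RR > 1) and negative for protective ones
(RR < 1). The contribution of a factor's prevalence change between baseline
year (BY) and end year (EY) is

    NX_i = NE(EY) * (PARF_i(EY) - PARF_i(BY))

under the sign convention used throughout this package: positive = fractures
generated by the change, negative = fractures prevented. (The alternative
orientation, in which a positive value denotes a decrease, is this quantity
negated; the convention is recorded in every result and run log.)

The osteoporosis-medication component multiplies treated-patient counts by the
relative risk reduction of the drug group and by the hip-fracture rate in
osteoporosis patients (population rate times the osteoporosis relative risk),
and counts as prevented (negative).

Because individual risk-factor attributions overlap, their sum is corrected by
the adjustment factor AF = CR / AR, the ratio of the cumulative risk change
CR = 1 - prod(1 - R_i) to the additive one AR = sum R_i. AF is applied to the
risk-factor and drug-class subtotals, never to the medication term. The
per-factor magnitude R_i defaults to |PARF(EY) - PARF(BY)| pooled across sex
strata by expected-count weighting; the end-year PARF magnitude is available
as an alternative interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from .expectation import (
    ExpectationResult,
    compute_expectation,
)
from .scenario import RATE_PER, FactorSpec, MedicationSpec, Scenario


def parf(prevalence: float, rr: float) -> float:
    """Population attributable risk fraction of a binary exposure."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    num = prevalence * (rr - 1.0)
    denom = num + 1.0
    if denom <= 0:
        raise ValueError(
            f"invalid PARF input: P(RR-1)+1 = {denom} <= 0 "
            f"(P={prevalence}, RR={rr})"
        )
    return num / denom


def factor_contribution(
    ne_ey: float, p_by: float, p_ey: float, rr: float
) -> float:
    """Fracture count attributable to a factor's prevalence change.

    Positive = generated by the change, negative = prevented.
    """
    if ne_ey < 0:
        raise ValueError(f"expected count must be >= 0, got {ne_ey}")
    return ne_ey * (parf(p_ey, rr) - parf(p_by, rr))


def osteoporosis_rate(pop_rate: float, osteo_rr: float) -> float:
    """Hip-fracture rate in osteoporosis patients (per 10,000).

    The whole-population rate multiplied by the relative risk of hip fracture
    in osteoporosis patients versus the whole population.
    """
    if pop_rate < 0 or osteo_rr < 0:
        raise ValueError("rate and relative risk must be >= 0")
    return pop_rate * osteo_rr


def medication_contribution(
    users: float, rrr: float, r_op: float, per: int = RATE_PER
) -> float:
    """Fractures prevented by an osteoporosis-medication group (negative).

    ``users`` treated patients times the relative risk reduction ``rrr`` times
    the osteoporosis hip-fracture rate ``r_op`` (per ``per``).
    """
    if users < 0:
        raise ValueError(f"users must be >= 0, got {users}")
    if not 0.0 <= rrr <= 1.0:
        raise ValueError(f"rrr must be in [0, 1], got {rrr}")
    if r_op < 0:
        raise ValueError(f"r_op must be >= 0, got {r_op}")
    return -(users * rrr * r_op / per)


@dataclass(frozen=True)
class AdjustmentInput:
    """Per-factor risk magnitudes feeding the overlap adjustment."""

    risk_magnitudes: list[float]
    interpretation: str = "delta_parf"

    def __post_init__(self) -> None:
        for r in self.risk_magnitudes:
            if not 0.0 <= r < 1.0:
                raise ValueError(
                    f"risk magnitude must be in [0, 1), got {r}"
                )


@dataclass(frozen=True)
class AdjustmentResult:
    af: float
    cr: float
    ar: float
    interpretation: str
    applied: bool = True
    note: str = ""


def adjustment_factor(inp: AdjustmentInput) -> AdjustmentResult:
    """Overlap adjustment AF = CR / AR in (0, 1].

    CR = 1 - prod(1 - R_i) (cumulative), AR = sum R_i (additive). With all
    magnitudes zero AF is defined as 1 by continuity (noted in the result).
    """
    if not inp.risk_magnitudes:
        raise ValueError("adjustment_factor needs at least one risk magnitude")
    if len(inp.risk_magnitudes) == 1:
        # CR == AR identically; AF is 1 regardless of the magnitude
        r = inp.risk_magnitudes[0]
        return AdjustmentResult(
            af=1.0, cr=r, ar=r, interpretation=inp.interpretation
        )
    # log1p/expm1 keeps CR/AR -> 1 accurate for very small magnitudes
    cr = -math.expm1(sum(math.log1p(-r) for r in inp.risk_magnitudes))
    ar = sum(inp.risk_magnitudes)
    if ar == 0.0:
        return AdjustmentResult(
            af=1.0,
            cr=0.0,
            ar=0.0,
            interpretation=inp.interpretation,
            note="all risk magnitudes zero; AF = 1 by continuity",
        )
    return AdjustmentResult(
        af=cr / ar, cr=cr, ar=ar, interpretation=inp.interpretation
    )


def risk_component(contributions: list[float], af: float) -> float:
    """Adjusted component total: AF times the sum of per-factor contributions."""
    if not 0.0 < af <= 1.0:
        raise ValueError(f"adjustment factor must be in (0, 1], got {af}")
    return af * sum(contributions)


def aggregate(
    nx_med: float, nx_risk_factors: float, nx_drugs: float, excess: float
) -> tuple[float, float]:
    """Total modeled excess and the percent of the estimated excess explained."""
    if excess == 0:
        raise ValueError("excess is zero; percent explained undefined")
    nx_modeled = nx_med + nx_risk_factors + nx_drugs
    return nx_modeled, 100.0 * nx_modeled / excess


def share_of_total(nx: float, excess: float) -> float:
    """Signed percent of the total excess contributed by one component."""
    if excess == 0:
        raise ValueError("excess is zero; share undefined")
    return 100.0 * nx / excess


# ---------------------------------------------------------------------------
# Scenario-level decomposition


Track = Literal["equations", "published"]

RISK_CATEGORIES = ("risk_factor", "preventive")


@dataclass(frozen=True)
class FactorContribution:
    factor: str
    sex: str
    category: str
    parf_by: float
    parf_ey: float
    nx: float
    share: float


@dataclass(frozen=True)
class MedicationContribution:
    medication: str
    sex: str
    r_op_by: float
    r_op_ey: float
    nx: float
    share: float


@dataclass(frozen=True)
class DecompositionResult:
    track: Track
    expectation: ExpectationResult
    contributions: list[FactorContribution]
    med_contributions: list[MedicationContribution]
    adjustment: Optional[AdjustmentResult]
    nx_med: float
    nx_risk: float
    nx_drugs: float
    nx_modeled: float
    percent_explained: float
    sensitivity: Optional[object] = None  # SensitivityResult, set by pipeline
    warnings: list[str] = field(default_factory=list)

    def factor_total(self, name: str) -> float:
        return sum(c.nx for c in self.contributions if c.factor == name)


def _equation_rows(
    scenario: Scenario, expectation: ExpectationResult
) -> list[FactorContribution]:
    excess = expectation.total_excess
    rows = []
    for f in scenario.factors:
        for s in scenario.strata:
            ne = expectation.stratum(s.sex).expected_ey
            pb = parf(f.prevalence_by[s.sex], f.relative_risk[s.sex])
            pe = parf(f.prevalence_ey[s.sex], f.relative_risk[s.sex])
            nx = ne * (pe - pb)
            rows.append(
                FactorContribution(
                    factor=f.name,
                    sex=s.sex,
                    category=f.category,
                    parf_by=pb,
                    parf_ey=pe,
                    nx=nx,
                    share=share_of_total(nx, excess) if excess else float("nan"),
                )
            )
    return rows


def _risk_magnitude(
    f: FactorSpec, scenario: Scenario, expectation: ExpectationResult, how: str
) -> float:
    """Per-factor overlap magnitude R_i pooled over strata by NE weight."""
    num = 0.0
    den = 0.0
    for s in scenario.strata:
        ne = expectation.stratum(s.sex).expected_ey
        rr = f.relative_risk[s.sex]
        if how == "delta_parf":
            mag = abs(
                parf(f.prevalence_ey[s.sex], rr) - parf(f.prevalence_by[s.sex], rr)
            )
        elif how == "parf_ey":
            mag = abs(parf(f.prevalence_ey[s.sex], rr))
        else:
            raise ValueError(f"unknown adjustment interpretation {how!r}")
        num += ne * mag
        den += ne
    mag = num / den if den else 0.0
    # PARF differences of valid inputs lie in (-1, 1); clip defensively.
    return min(mag, math.nextafter(1.0, 0.0))


def _medication_rows(
    scenario: Scenario, expectation: ExpectationResult
) -> list[MedicationContribution]:
    excess = expectation.total_excess
    rows = []
    for m in scenario.medications:
        for s in scenario.strata:
            exp = expectation.stratum(s.sex)
            r_op_by = osteoporosis_rate(exp.rate_by, m.osteo_rr[s.sex])
            r_op_ey = osteoporosis_rate(exp.rate_ey, m.osteo_rr[s.sex])
            nx = medication_contribution(m.users_ey[s.sex], m.rrr, r_op_ey)
            rows.append(
                MedicationContribution(
                    medication=m.name,
                    sex=s.sex,
                    r_op_by=r_op_by,
                    r_op_ey=r_op_ey,
                    nx=nx,
                    share=share_of_total(nx, excess) if excess else float("nan"),
                )
            )
    return rows


def _published_rows(
    scenario: Scenario, expectation: ExpectationResult
) -> tuple[list[FactorContribution], list[MedicationContribution]]:
    excess = expectation.total_excess
    frows = []
    for f in scenario.factors:
        if f.reported is None:
            raise ValueError(
                f"factor {f.name!r} has no reported values; "
                "published track unavailable"
            )
        for s in scenario.strata:
            if s.sex not in f.reported.nx:
                raise ValueError(
                    f"factor {f.name!r}: no reported value for sex {s.sex!r}"
                )
            nx = f.reported.nx[s.sex]
            rr = f.relative_risk[s.sex]
            frows.append(
                FactorContribution(
                    factor=f.name,
                    sex=s.sex,
                    category=f.category,
                    parf_by=parf(f.prevalence_by[s.sex], rr),
                    parf_ey=parf(f.prevalence_ey[s.sex], rr),
                    nx=nx,
                    share=share_of_total(nx, excess) if excess else float("nan"),
                )
            )
    mrows = []
    for m in scenario.medications:
        if m.reported is None:
            raise ValueError(
                f"medication {m.name!r} has no reported values; "
                "published track unavailable"
            )
        for s in scenario.strata:
            exp = expectation.stratum(s.sex)
            nx = m.reported.nx[s.sex]
            mrows.append(
                MedicationContribution(
                    medication=m.name,
                    sex=s.sex,
                    r_op_by=osteoporosis_rate(exp.rate_by, m.osteo_rr[s.sex]),
                    r_op_ey=osteoporosis_rate(exp.rate_ey, m.osteo_rr[s.sex]),
                    nx=nx,
                    share=share_of_total(nx, excess) if excess else float("nan"),
                )
            )
    return frows, mrows


def decompose(
    scenario: Scenario,
    track: Track = "equations",
    expectation: Optional[ExpectationResult] = None,
) -> DecompositionResult:
    """Run the full decomposition of a scenario on one track.

    ``equations`` recomputes every contribution from prevalences, relative
    risks and medication inputs; the overlap adjustment is applied to the
    risk-factor and drug subtotals. ``published`` aggregates the reported
    per-row values carried by a fixture scenario (the adjustment factor is
    still computed and reported, but not applied, since reported rows already
    sum to their reported totals).
    """
    if expectation is None:
        expectation = compute_expectation(scenario)
    excess = expectation.total_excess
    warnings: list[str] = []

    how = scenario.options.adjustment_interpretation
    adjustment = None
    if scenario.factors:
        mags = [
            _risk_magnitude(f, scenario, expectation, how)
            for f in scenario.factors
        ]
        adjustment = adjustment_factor(
            AdjustmentInput(risk_magnitudes=mags, interpretation=how)
        )
        if adjustment.note:
            warnings.append(adjustment.note)

    if track == "equations":
        frows = _equation_rows(scenario, expectation)
        mrows = _medication_rows(scenario, expectation)
        af = adjustment.af if adjustment else 1.0
        raw_risk = sum(
            c.nx for c in frows if c.category in RISK_CATEGORIES
        )
        raw_drugs = sum(c.nx for c in frows if c.category == "drug_side_effect")
        nx_risk = af * raw_risk
        nx_drugs = af * raw_drugs
        if adjustment:
            adjustment = AdjustmentResult(
                af=adjustment.af,
                cr=adjustment.cr,
                ar=adjustment.ar,
                interpretation=adjustment.interpretation,
                applied=True,
                note=adjustment.note,
            )
    elif track == "published":
        frows, mrows = _published_rows(scenario, expectation)
        nx_risk = sum(c.nx for c in frows if c.category in RISK_CATEGORIES)
        nx_drugs = sum(c.nx for c in frows if c.category == "drug_side_effect")
        if adjustment:
            adjustment = AdjustmentResult(
                af=adjustment.af,
                cr=adjustment.cr,
                ar=adjustment.ar,
                interpretation=adjustment.interpretation,
                applied=False,
                note="published track: AF reported, not applied to reported rows",
            )
            warnings.append(adjustment.note)
    else:
        raise ValueError(f"unknown track {track!r}")

    nx_med = sum(c.nx for c in mrows)
    if excess != 0:
        nx_modeled, percent = aggregate(nx_med, nx_risk, nx_drugs, excess)
    else:
        nx_modeled = nx_med + nx_risk + nx_drugs
        percent = float("nan")
        warnings.append("excess is zero; percent explained undefined")

    return DecompositionResult(
        track=track,
        expectation=expectation,
        contributions=frows,
        med_contributions=mrows,
        adjustment=adjustment,
        nx_med=nx_med,
        nx_risk=nx_risk,
        nx_drugs=nx_drugs,
        nx_modeled=nx_modeled,
        percent_explained=percent,
        warnings=warnings,
    )
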