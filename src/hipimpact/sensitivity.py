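"""Extremes (multidirectional) sensitivity analysis.

Every model parameter — prevalences, relative risks, medication user counts,
relative risk reduction, osteoporosis relative risks — is assigned a lower and
an upper value: a supplied 95% confidence interval where available, otherwise
the central value +/- 20% (prevalences clipped to [0, 1]). The model is then
evaluated with parameters set jointly to their extremes to bracket the modeled
(explained) excess:

* ``enumeration`` evaluates every corner of the bound hypercube (practical up
  to 20 varied parameters);
* ``monotone`` probes each parameter once to find the direction in which it
  moves the output, then evaluates the joint maximising and minimising corner.

On models where every parameter acts monotonically the two modes agree
exactly. Both modes include the central (best-estimate) evaluation among the
candidates, so the reported bracket always contains the best estimate.
Correlated bounds (e.g. the BY and EY prevalence of one factor) are varied
independently — a documented limitation. A one-at-a-time tornado table is
emitted alongside as a diagnostic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

from .attribution import decompose
from .scenario import (
    FactorSpec,
    MedicationSpec,
    Scenario,
    UncertaintyBounds,
)

Mode = Literal["enumeration", "monotone"]

ENUMERATION_LIMIT = 20

# Parameter fields that enter the model, per spec kind.
_FACTOR_FIELDS = ("prevalence_by", "prevalence_ey", "relative_risk")
# users_by is data carried for reporting; the end-year formulation of the
# medication component does not consume it, so it is not varied.
_MED_FIELDS = ("users_ey", "rrr", "osteo_rr")

# proportion-valued fields whose default bounds are clipped to [0, 1]
_PROPORTION_FIELDS = {"prevalence_by", "prevalence_ey", "rrr"}


def default_bounds(
    central: float, kind: str, supplied: Optional[UncertaintyBounds] = None
) -> UncertaintyBounds:
    """Bounds for one parameter: supplied CI if present, else +/- 20%.

    ``kind`` is the field name; prevalence bounds are clipped to [0, 1].
    """
    if supplied is not None:
        return supplied
    low, high = central * 0.8, central * 1.2
    if kind in _PROPORTION_FIELDS:
        low, high = max(0.0, low), min(1.0, high)
    return UncertaintyBounds(low=low, high=high, source="pct20")


@dataclass(frozen=True, eq=False)  # identity hash: instances key assignments
class Parameter:
    """Address of one varied scalar in a scenario, with its bounds."""

    block: Literal["factor", "medication"]
    name: str
    fld: str
    sex: Optional[str]  # None for scalar fields (rrr) or shared per-sex values
    central: float
    bounds: UncertaintyBounds

    @property
    def label(self) -> str:
        sx = f"[{self.sex}]" if self.sex else ""
        return f"{self.block}:{self.name}.{self.fld}{sx}"


def _spec_parameters(
    spec: Union[FactorSpec, MedicationSpec], block: str, fields: tuple[str, ...]
) -> list[Parameter]:
    params: list[Parameter] = []
    for fld in fields:
        value = getattr(spec, fld)
        supplied = spec.bounds.get(fld, {})
        if isinstance(value, float):  # scalar field (rrr)
            params.append(
                Parameter(
                    block=block,  # type: ignore[arg-type]
                    name=spec.name,
                    fld=fld,
                    sex=None,
                    central=value,
                    bounds=default_bounds(value, fld, supplied.get("*")),
                )
            )
            continue
        if value.shared:
            sexes: list[Optional[str]] = [None]
        else:
            sexes = list(value.by_sex)
        for sex in sexes:
            if sex is None:
                central = next(iter(value.by_sex.values()))
                # shared "*" bounds were expanded per sex at validation; all
                # entries are equal, so any one applies to the shared parameter
                sup = next(iter(supplied.values())) if supplied else None
            else:
                central = value[sex]
                sup = supplied.get(sex)
            params.append(
                Parameter(
                    block=block,  # type: ignore[arg-type]
                    name=spec.name,
                    fld=fld,
                    sex=sex,
                    central=central,
                    bounds=default_bounds(central, fld, sup),
                )
            )
    return params


def build_parameters(scenario: Scenario) -> list[Parameter]:
    """Flatten every varied model parameter of a scenario, with bounds."""
    params: list[Parameter] = []
    for f in scenario.factors:
        params.extend(_spec_parameters(f, "factor", _FACTOR_FIELDS))
    for m in scenario.medications:
        params.extend(_spec_parameters(m, "medication", _MED_FIELDS))
    return params


def _apply(scenario: Scenario, assignment: dict[Parameter, float]) -> Scenario:
    """Return a deep copy of the scenario with assigned parameter values."""
    out = scenario.model_copy(deep=True)
    blocks = {"factor": {f.name: f for f in out.factors},
              "medication": {m.name: m for m in out.medications}}
    for p, v in assignment.items():
        spec = blocks[p.block][p.name]
        value = getattr(spec, p.fld)
        if isinstance(value, float):
            setattr(spec, p.fld, v)
        elif p.sex is None:
            value.by_sex = {sex: v for sex in value.by_sex}
        else:
            value.by_sex[p.sex] = v
    return out


def _evaluate(scenario: Scenario, assignment: dict[Parameter, float]) -> float:
    """Modeled excess (explained count) at one parameter assignment."""
    return decompose(_apply(scenario, assignment), track="equations").nx_modeled


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_output: float
    high_output: float


@dataclass(frozen=True)
class SensitivityResult:
    mode: Mode
    best_estimate: float
    min_explained: float
    max_explained: float
    min_percent: float
    max_percent: float
    per_component_ranges: dict[str, tuple[float, float]]
    tornado: list[TornadoEntry] = field(default_factory=list)
    n_parameters: int = 0


def _component_ranges(
    scenario: Scenario, params: list[Parameter]
) -> dict[str, tuple[float, float]]:
    """Per factor/medication: range of its own total over its own corners."""
    ranges: dict[str, tuple[float, float]] = {}
    by_spec: dict[tuple[str, str], list[Parameter]] = {}
    for p in params:
        by_spec.setdefault((p.block, p.name), []).append(p)
    for (block, name), own in by_spec.items():
        values: list[float] = []
        for corner in itertools.product(*[(p.bounds.low, p.bounds.high) for p in own]):
            res = decompose(
                _apply(scenario, dict(zip(own, corner))), track="equations"
            )
            if block == "factor":
                values.append(res.factor_total(name))
            else:
                values.append(
                    sum(c.nx for c in res.med_contributions if c.medication == name)
                )
        central = decompose(scenario, track="equations")
        if block == "factor":
            values.append(central.factor_total(name))
        else:
            values.append(
                sum(c.nx for c in central.med_contributions if c.medication == name)
            )
        ranges[f"{block}:{name}"] = (min(values), max(values))
    return ranges


def extremes_analysis(
    scenario: Scenario,
    mode: Mode = "monotone",
    component_ranges: bool = True,
) -> SensitivityResult:
    """Bracket the modeled excess over the joint parameter-bound hypercube."""
    params = build_parameters(scenario)
    excess = decompose(scenario, track="equations").expectation.total_excess
    best = _evaluate(scenario, {})
    tornado: list[TornadoEntry] = []

    if not params:
        lo = hi = best
    elif mode == "enumeration":
        if len(params) > ENUMERATION_LIMIT:
            raise ValueError(
                f"enumeration over {len(params)} parameters exceeds the "
                f"{ENUMERATION_LIMIT}-parameter limit; use mode='monotone'"
            )
        values = [
            _evaluate(scenario, dict(zip(params, corner)))
            for corner in itertools.product(
                *[(p.bounds.low, p.bounds.high) for p in params]
            )
        ]
        values.append(best)
        lo, hi = min(values), max(values)
    elif mode == "monotone":
        up: dict[Parameter, float] = {}
        down: dict[Parameter, float] = {}
        for p in params:
            f_low = _evaluate(scenario, {p: p.bounds.low})
            f_high = _evaluate(scenario, {p: p.bounds.high})
            tornado.append(
                TornadoEntry(parameter=p.label, low_output=f_low, high_output=f_high)
            )
            if f_high >= f_low:
                up[p], down[p] = p.bounds.high, p.bounds.low
            else:
                up[p], down[p] = p.bounds.low, p.bounds.high
        hi = max(_evaluate(scenario, up), best)
        lo = min(_evaluate(scenario, down), best)
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")

    comp = _component_ranges(scenario, params) if component_ranges else {}
    if excess:
        min_pct, max_pct = 100.0 * lo / excess, 100.0 * hi / excess
        if min_pct > max_pct:  # negative excess flips the percent ordering
            min_pct, max_pct = max_pct, min_pct
    else:
        min_pct = max_pct = float("nan")
    return SensitivityResult(
        mode=mode,
        best_estimate=best,
        min_explained=lo,
        max_explained=hi,
        min_percent=min_pct,
        max_percent=max_pct,
        per_component_ranges=comp,
        tornado=tornado,
        n_parameters=len(params),
    )
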