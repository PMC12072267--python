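"""Scenario domain types, validation, and YAML round-trip I/O.

A :class:`Scenario` is the complete input of the decomposition model: two (or
more) sex strata with populations and observed fracture counts at a baseline
year (BY) and an end year (EY), a set of binary exposures (risk factors,
preventive measures, drug classes with skeletal side effects) with per-sex
prevalences and relative risks, and one or more osteoporosis-medication
groups. Prevalences are proportions in [0, 1]; rates are carried per 10,000
person-denominator throughout.

Per-sex fields may be written as a plain scalar in the config file; the reader
expands the shared value to every stratum and flags it, so that downstream
code (e.g. the sensitivity module) can treat it as a single parameter.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

RATE_PER = 10_000  # rate denominator used everywhere (per 10,000 inhabitants)

SHARED_KEY = "*"

Category = Literal["risk_factor", "preventive", "drug_side_effect"]


class ScenarioError(ValueError):
    """Raised for unparsable or invalid scenario configuration."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class UncertaintyBounds(_StrictModel):
    """A lower/upper pair for one parameter.

    ``source`` records where the pair came from: a published 95% confidence
    interval (``ci95``), the default central-value +/- 20% rule (``pct20``),
    or a user-supplied custom pair.
    """

    low: float
    high: float
    source: Literal["ci95", "pct20", "custom"] = "custom"

    @model_validator(mode="before")
    @classmethod
    def _from_pair(cls, v: Any) -> Any:
        # YAML shorthand: a two-element list is an explicit (CI) bound pair.
        if isinstance(v, (list, tuple)):
            if len(v) != 2:
                raise ValueError("bounds pair must have exactly two elements")
            return {"low": v[0], "high": v[1], "source": "ci95"}
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "UncertaintyBounds":
        if self.low > self.high:
            raise ValueError(f"bounds low > high ({self.low} > {self.high})")
        return self

    @property
    def width(self) -> float:
        return self.high - self.low


class PerSex(_StrictModel):
    """A value given per sex stratum, or one shared value expanded to all.

    ``by_sex`` maps stratum labels to values. A scalar in the config file
    (or the key ``"*"``) denotes a shared value; the scenario validator
    expands it to every stratum label and sets ``shared``.
    """

    by_sex: dict[str, float]
    shared: bool = False

    @model_validator(mode="before")
    @classmethod
    def _from_scalar(cls, v: Any) -> Any:
        if isinstance(v, (int, float)):
            return {"by_sex": {SHARED_KEY: float(v)}, "shared": True}
        if isinstance(v, dict) and "by_sex" not in v:
            return {"by_sex": v}
        return v

    def __getitem__(self, sex: str) -> float:
        return self.by_sex[sex]

    def value_for(self, sex: str) -> float:
        return self.by_sex[sex]


class ReportedOutcome(_StrictModel):
    """Published per-row results attached to a fixture factor/medication.

    These are carried as annotations (keys: stratum labels plus ``total``)
    and drive the "published" aggregation track; they are never inputs to
    the equation-based computation.
    """

    nx: dict[str, float]
    nx_range: Optional[dict[str, UncertaintyBounds]] = None
    share: Optional[dict[str, float]] = None


class FactorSpec(_StrictModel):
    """One binary exposure: prevalences at BY/EY and a relative risk, per sex."""

    name: str
    category: Category
    prevalence_by: PerSex
    prevalence_ey: PerSex
    relative_risk: PerSex
    bounds: dict[str, dict[str, UncertaintyBounds]] = {}
    reported: Optional[ReportedOutcome] = None

    @model_validator(mode="after")
    def _ranges(self) -> "FactorSpec":
        for field in ("prevalence_by", "prevalence_ey"):
            for sex, p in getattr(self, field).by_sex.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"factor {self.name!r}: {field}[{sex}] = {p} "
                        "outside [0, 1]"
                    )
        for sex, rr in self.relative_risk.by_sex.items():
            if rr <= 0:
                raise ValueError(
                    f"factor {self.name!r}: relative_risk[{sex}] = {rr} <= 0"
                )
        known = {"prevalence_by", "prevalence_ey", "relative_risk"}
        for key in self.bounds:
            if key not in known:
                raise ValueError(
                    f"factor {self.name!r}: bounds for unknown parameter {key!r}"
                )
        return self


class MedicationSpec(_StrictModel):
    """Osteoporosis-medication component inputs.

    ``users_by``/``users_ey`` are treated-patient counts at baseline and end
    year; ``rrr`` is the relative risk reduction of the drug group (fraction);
    ``osteo_rr`` is the relative risk of hip fracture in osteoporosis patients
    versus the whole population, per sex.
    """

    name: str
    users_by: PerSex
    users_ey: PerSex
    rrr: float
    osteo_rr: PerSex
    bounds: dict[str, dict[str, UncertaintyBounds]] = {}
    reported: Optional[ReportedOutcome] = None

    @model_validator(mode="after")
    def _ranges(self) -> "MedicationSpec":
        for field in ("users_by", "users_ey"):
            for sex, u in getattr(self, field).by_sex.items():
                if u < 0:
                    raise ValueError(
                        f"medication {self.name!r}: {field}[{sex}] = {u} < 0"
                    )
        if not 0.0 <= self.rrr <= 1.0:
            raise ValueError(
                f"medication {self.name!r}: rrr = {self.rrr} outside [0, 1]"
            )
        for sex, rr in self.osteo_rr.by_sex.items():
            if rr < 1.0:
                raise ValueError(
                    f"medication {self.name!r}: osteo_rr[{sex}] = {rr} < 1"
                )
        known = {"users_by", "users_ey", "rrr", "osteo_rr"}
        for key in self.bounds:
            if key not in known:
                raise ValueError(
                    f"medication {self.name!r}: bounds for unknown parameter "
                    f"{key!r}"
                )
        return self


class StratumRecord(_StrictModel):
    """One sex stratum: population and observed fracture counts at BY and EY.

    ``rate_by`` optionally overrides the recomputed baseline rate (per 10,000)
    — used when a published scenario's downstream numbers were produced from a
    rounded printed rate rather than the exact count ratio.
    """

    sex: str
    pop_by: float
    pop_ey: float
    observed_by: float
    observed_ey: float
    rate_by: Optional[float] = None

    @model_validator(mode="after")
    def _ranges(self) -> "StratumRecord":
        if self.pop_by <= 0 or self.pop_ey <= 0:
            raise ValueError(f"stratum {self.sex!r}: population must be > 0")
        if self.observed_by < 0 or self.observed_ey < 0:
            raise ValueError(
                f"stratum {self.sex!r}: observed counts must be >= 0"
            )
        if self.observed_by > self.pop_by or self.observed_ey > self.pop_ey:
            raise ValueError(
                f"stratum {self.sex!r}: observed counts exceed population"
            )
        if self.rate_by is not None and self.rate_by < 0:
            raise ValueError(f"stratum {self.sex!r}: rate_by must be >= 0")
        return self


class ScenarioOptions(_StrictModel):
    """Fixed-default knobs of a run; every value is echoed into the run log."""

    interval_method: Literal["exact", "normal"] = "exact"
    interval_level: float = 0.95
    adjustment_interpretation: Literal["delta_parf", "parf_ey"] = "delta_parf"
    sign_convention: Literal["generated_positive"] = "generated_positive"
    rate_decimals: int = 2
    percent_decimals: int = 1


class Scenario(_StrictModel):
    """Complete model input for one country/period comparison."""

    baseline_year: int
    end_year: int
    strata: list[StratumRecord]
    factors: list[FactorSpec] = []
    medications: list[MedicationSpec] = []
    options: ScenarioOptions = ScenarioOptions()

    @model_validator(mode="after")
    def _consistent(self) -> "Scenario":
        if self.end_year <= self.baseline_year:
            raise ValueError(
                f"end_year {self.end_year} must be after baseline_year "
                f"{self.baseline_year}"
            )
        if not self.strata:
            raise ValueError("at least one stratum is required")
        sexes = [s.sex for s in self.strata]
        if len(set(sexes)) != len(sexes):
            raise ValueError("stratum sex labels must be unique")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        for f in self.factors:
            for field in ("prevalence_by", "prevalence_ey", "relative_risk"):
                _expand_shared(getattr(f, field), sexes, f"factor {f.name!r}.{field}")
            _expand_bounds(f.bounds, sexes, f"factor {f.name!r}")
        for m in self.medications:
            for field in ("users_by", "users_ey", "osteo_rr"):
                _expand_shared(
                    getattr(m, field), sexes, f"medication {m.name!r}.{field}"
                )
            _expand_bounds(m.bounds, sexes, f"medication {m.name!r}")
        return self

    @property
    def sexes(self) -> list[str]:
        return [s.sex for s in self.strata]

    def stratum(self, sex: str) -> StratumRecord:
        for s in self.strata:
            if s.sex == sex:
                return s
        raise KeyError(sex)


def _expand_shared(value: PerSex, sexes: list[str], where: str) -> None:
    """Expand a shared (``*``) per-sex value to every stratum label, in place."""
    if SHARED_KEY in value.by_sex:
        if len(value.by_sex) != 1:
            raise ValueError(f"{where}: mix of shared and per-sex values")
        v = value.by_sex[SHARED_KEY]
        value.by_sex = {sex: v for sex in sexes}
        value.shared = True
    else:
        missing = [s for s in sexes if s not in value.by_sex]
        unknown = [s for s in value.by_sex if s not in sexes]
        if missing or unknown:
            raise ValueError(
                f"{where}: per-sex keys {sorted(value.by_sex)} do not match "
                f"strata {sexes}"
            )


def _expand_bounds(
    bounds: dict[str, dict[str, UncertaintyBounds]],
    sexes: list[str],
    where: str,
) -> None:
    for param, per_sex in bounds.items():
        if SHARED_KEY in per_sex:
            if len(per_sex) != 1:
                raise ValueError(
                    f"{where}: bounds[{param!r}] mixes shared and per-sex"
                )
            b = per_sex[SHARED_KEY]
            per_sex.clear()
            per_sex.update({sex: b.model_copy() for sex in sexes})


def read_scenario(path: str | Path) -> Scenario:
    """Read and validate a scenario from a YAML file.

    Raises :class:`ScenarioError` naming the offending field on parse failure,
    invariant violation, or unknown keys.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ScenarioError(f"scenario file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ScenarioError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioError(f"{path}: top level must be a mapping")
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict) -> Scenario:
    try:
        return Scenario.model_validate(raw)
    except ValidationError as exc:
        # Surface pydantic's field-located messages under the package error.
        raise ScenarioError(str(exc)) from exc


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario back to YAML such that it round-trips exactly."""
    Path(path).write_text(
        yaml.safe_dump(
            scenario.model_dump(mode="json"), sort_keys=False, allow_unicode=True
        )
    )
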