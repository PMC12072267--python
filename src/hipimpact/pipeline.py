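"""Pipeline driver: run expectation -> attribution -> sensitivity and write
the result set (JSON summary, per-table CSVs, plain-text run log).

For annotated fixtures two tracks are reported side by side: ``published``
aggregates the reported per-row values carried by the scenario (and reproduces
their printed totals exactly), while ``equations`` recomputes every row from
prevalences and relative risks (and is documented as diverging from the
published rows, which rest on unprinted stratified inputs).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .attribution import (
    RISK_CATEGORIES,
    DecompositionResult,
    decompose,
)
from .expectation import compute_expectation, round_half_away
from .scenario import Scenario, read_scenario
from .sensitivity import SensitivityResult, extremes_analysis


class RunConfig(BaseModel):
    """Everything one pipeline invocation depends on."""

    model_config = ConfigDict(extra="forbid")

    scenario_path: Optional[str] = None  # None: use an in-memory scenario
    out_dir: Optional[str] = None
    track: Literal["equations", "published", "both"] = "both"
    sensitivity: Literal["enumeration", "monotone", "off"] = "monotone"
    seed: Optional[int] = None
    verbosity: int = 1


@dataclasses.dataclass
class PipelineResult:
    scenario: Scenario
    results: dict[str, DecompositionResult]  # keyed by track
    sensitivity: Optional[SensitivityResult]
    log: list[str]
    written: list[Path] = dataclasses.field(default_factory=list)

    @property
    def primary(self) -> DecompositionResult:
        for track in ("published", "equations"):
            if track in self.results:
                return self.results[track]
        raise RuntimeError("no decomposition track produced")


def run_pipeline(
    config: RunConfig, scenario: Optional[Scenario] = None
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write all artifacts."""
    if scenario is None:
        if config.scenario_path is None:
            raise ValueError("either a scenario or a scenario_path is required")
        scenario = read_scenario(config.scenario_path)

    log: list[str] = []
    opts = scenario.options
    log.append(f"scenario: {config.scenario_path or '<in-memory>'}")
    log.append(
        f"period: {scenario.baseline_year}-{scenario.end_year}; "
        f"strata: {', '.join(scenario.sexes)}; "
        f"factors: {len(scenario.factors)}; medications: {len(scenario.medications)}"
    )
    log.append(
        "units: prevalences as proportions in [0, 1] (percent inputs divided "
        "by 100 upstream); rates per 10,000 inhabitants"
    )
    for key, value in opts.model_dump().items():
        log.append(f"option {key} = {value}")
    log.append(
        "sign convention: positive = fractures generated by the change, "
        "negative = prevented (table orientation)"
    )

    expectation = compute_expectation(scenario)
    tracks = (
        ["equations", "published"] if config.track == "both" else [config.track]
    )
    results: dict[str, DecompositionResult] = {}
    for track in tracks:
        try:
            results[track] = decompose(
                scenario, track=track, expectation=expectation
            )
        except ValueError as exc:
            if track == "published" and config.track == "both":
                log.append(f"published track skipped: {exc}")
            else:
                raise
    for track, res in results.items():
        for w in res.warnings:
            log.append(f"[{track}] {w}")
        if res.adjustment:
            log.append(
                f"[{track}] adjustment factor AF = {res.adjustment.af:.6f} "
                f"(CR = {res.adjustment.cr:.6f}, AR = {res.adjustment.ar:.6f}, "
                f"R_i = {res.adjustment.interpretation}, "
                f"applied = {res.adjustment.applied})"
            )

    sens = None
    if config.sensitivity != "off":
        sens = extremes_analysis(scenario, mode=config.sensitivity)
        log.append(
            f"sensitivity ({sens.mode}, {sens.n_parameters} parameters): "
            f"explained in [{sens.min_explained:.1f}, {sens.max_explained:.1f}] "
            f"({sens.min_percent:.1f}% to {sens.max_percent:.1f}%)"
        )
        if "equations" in results:
            results["equations"] = dataclasses.replace(
                results["equations"], sensitivity=sens
            )

    result = PipelineResult(
        scenario=scenario, results=results, sensitivity=sens, log=log
    )
    if config.out_dir is not None:
        result.written = write_results(result, Path(config.out_dir))
    return result


# ---------------------------------------------------------------------------
# Output writers


def _sens_payload(sens: Optional[SensitivityResult]) -> Optional[dict]:
    if sens is None:
        return None
    return {
        "mode": sens.mode,
        "n_parameters": sens.n_parameters,
        "best_estimate": sens.best_estimate,
        "min_explained": sens.min_explained,
        "max_explained": sens.max_explained,
        "min_percent": sens.min_percent,
        "max_percent": sens.max_percent,
        "per_component_ranges": {
            k: list(v) for k, v in sorted(sens.per_component_ranges.items())
        },
    }


def summary_payload(result: PipelineResult) -> dict:
    """JSON-ready summary of every track (deterministic key order)."""
    payload: dict = {"tracks": {}, "options": result.scenario.options.model_dump()}
    for track, res in sorted(result.results.items()):
        exp = res.expectation
        payload["tracks"][track] = {
            "expectation": {
                "strata": [
                    {
                        "sex": s.sex,
                        "rate_by": s.rate_by,
                        "rate_ey": s.rate_ey,
                        "expected_ey": s.expected_ey,
                        "excess": s.excess,
                        "ci_low": s.interval_ne.low,
                        "ci_high": s.interval_ne.high,
                    }
                    for s in exp.strata
                ],
                "total_expected": exp.total_expected,
                "total_observed": exp.total_observed,
                "total_excess": exp.total_excess,
                "gof_chi2": exp.gof.chi2 if exp.gof else None,
                "gof_df": exp.gof.df if exp.gof else None,
                "gof_pvalue": exp.gof.pvalue if exp.gof else None,
            },
            "factors": [dataclasses.asdict(c) for c in res.contributions],
            "medications": [dataclasses.asdict(c) for c in res.med_contributions],
            "adjustment": dataclasses.asdict(res.adjustment)
            if res.adjustment
            else None,
            "nx_med": res.nx_med,
            "nx_risk": res.nx_risk,
            "nx_drugs": res.nx_drugs,
            "nx_modeled": res.nx_modeled,
            "percent_explained": res.percent_explained,
        }
    payload["sensitivity"] = _sens_payload(result.sensitivity)
    return payload


def _expectation_frame(result: PipelineResult) -> pd.DataFrame:
    scenario = result.scenario
    exp = next(iter(result.results.values())).expectation
    nd = scenario.options.rate_decimals
    rows = []
    for s in scenario.strata:
        e = exp.stratum(s.sex)
        rows.append(
            {
                "stratum": s.sex,
                "population_by": s.pop_by,
                "observed_by": s.observed_by,
                "rate_by_per_10000": round_half_away(e.rate_by, nd),
                "population_ey": s.pop_ey,
                "observed_ey": s.observed_ey,
                "rate_ey_per_10000": round_half_away(e.rate_ey, nd),
                "expected_ey": e.expected_ey,
                "excess": e.excess,
                "expected_ci_low": round_half_away(e.interval_ne.low, 1),
                "expected_ci_high": round_half_away(e.interval_ne.high, 1),
            }
        )
    pop_by = sum(s.pop_by for s in scenario.strata)
    pop_ey = sum(s.pop_ey for s in scenario.strata)
    obs_by = sum(s.observed_by for s in scenario.strata)
    rows.append(
        {
            "stratum": "total",
            "population_by": pop_by,
            "observed_by": obs_by,
            "rate_by_per_10000": round_half_away(obs_by / pop_by * 10_000, nd),
            "population_ey": pop_ey,
            "observed_ey": exp.total_observed,
            "rate_ey_per_10000": round_half_away(
                exp.total_observed / pop_ey * 10_000, nd
            ),
            "expected_ey": exp.total_expected,
            "excess": exp.total_excess,
            "expected_ci_low": float("nan"),
            "expected_ci_high": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def _factor_frame(result: PipelineResult, categories: tuple[str, ...]) -> pd.DataFrame:
    scenario = result.scenario
    tracks = result.results
    sens = result.sensitivity
    rows = []
    total_by_track = {t: 0.0 for t in tracks}
    for f in scenario.factors:
        if f.category not in categories:
            continue
        for sex in scenario.sexes:
            row = {
                "factor": f.name,
                "category": f.category,
                "sex": sex,
                "prevalence_by": f.prevalence_by[sex],
                "prevalence_ey": f.prevalence_ey[sex],
                "relative_risk": f.relative_risk[sex],
            }
            for track, res in tracks.items():
                match = [
                    c
                    for c in res.contributions
                    if c.factor == f.name and c.sex == sex
                ]
                row[f"nx_{track}"] = match[0].nx if match else float("nan")
                row[f"share_{track}"] = match[0].share if match else float("nan")
            rows.append(row)
        for track, res in tracks.items():
            total_by_track[track] += res.factor_total(f.name)
        total_row = {
            "factor": f.name,
            "category": f.category,
            "sex": "total",
            "prevalence_by": float("nan"),
            "prevalence_ey": float("nan"),
            "relative_risk": float("nan"),
        }
        for track, res in tracks.items():
            nx = res.factor_total(f.name)
            total_row[f"nx_{track}"] = nx
            excess = res.expectation.total_excess
            total_row[f"share_{track}"] = (
                100.0 * nx / excess if excess else float("nan")
            )
        if sens is not None:
            key = f"factor:{f.name}"
            if key in sens.per_component_ranges:
                lo, hi = sens.per_component_ranges[key]
                total_row["nx_low"] = lo
                total_row["nx_high"] = hi
        rows.append(total_row)
    grand = {
        "factor": "TOTAL",
        "category": "+".join(categories),
        "sex": "total",
    }
    for track in tracks:
        grand[f"nx_{track}"] = total_by_track[track]
        excess = tracks[track].expectation.total_excess
        grand[f"share_{track}"] = (
            100.0 * total_by_track[track] / excess if excess else float("nan")
        )
    rows.append(grand)
    return pd.DataFrame(rows)


def _medication_frame(result: PipelineResult) -> pd.DataFrame:
    scenario = result.scenario
    tracks = result.results
    nd = scenario.options.rate_decimals
    rows = []
    for m in scenario.medications:
        for sex in scenario.sexes:
            row = {
                "medication": m.name,
                "sex": sex,
                "osteo_rr": m.osteo_rr[sex],
                "users_by": m.users_by[sex],
                "users_ey": m.users_ey[sex],
                "rrr": m.rrr,
            }
            for track, res in tracks.items():
                match = [
                    c
                    for c in res.med_contributions
                    if c.medication == m.name and c.sex == sex
                ]
                if match:
                    row["osteo_rate_by"] = round_half_away(match[0].r_op_by, nd)
                    row["osteo_rate_ey"] = round_half_away(match[0].r_op_ey, nd)
                    row[f"nx_{track}"] = match[0].nx
                    row[f"share_{track}"] = match[0].share
            rows.append(row)
        total_row = {"medication": m.name, "sex": "total", "rrr": m.rrr}
        for track, res in tracks.items():
            nx = sum(
                c.nx for c in res.med_contributions if c.medication == m.name
            )
            total_row[f"nx_{track}"] = nx
            excess = res.expectation.total_excess
            total_row[f"share_{track}"] = (
                100.0 * nx / excess if excess else float("nan")
            )
        rows.append(total_row)
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, out_dir: Path) -> list[Path]:
    """Write summary JSON, the four table-shaped CSVs, and the run log."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written = []

    summary = out_dir / "summary.json"
    summary.write_text(
        json.dumps(summary_payload(result), indent=2, sort_keys=True) + "\n"
    )
    written.append(summary)

    frames = {
        "expectation.csv": _expectation_frame(result),
        "medication.csv": _medication_frame(result),
        "risk_factors.csv": _factor_frame(result, RISK_CATEGORIES),
        "drug_side_effects.csv": _factor_frame(result, ("drug_side_effect",)),
    }
    for name, frame in frames.items():
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)

    log = out_dir / "run.log"
    log.write_text("\n".join(result.log) + "\n")
    written.append(log)
    return written
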