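"""Baseline-rate expectation: rates, expected end-year counts, the excess.

The excess to explain is the difference between the fractures observed in the
end year and the count expected had the baseline-year incidence rate persisted
in the end-year population:

    NX_estimated = NO(EY) - NE,   NE = r(BY) * pop(EY)

Rates are per 10,000 inhabitants. Expected counts are rounded
half-away-from-zero per stratum and the rounded values summed for totals.
Uncertainty on NE uses Poisson assumptions (exact Garwood inversion by
default, normal approximation by flag), and a chi-square goodness-of-fit test
compares observed end-year counts with the expected ones across strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .scenario import RATE_PER, Scenario, UncertaintyBounds


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for all displayed values)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def incidence_rate(count: float, population: float, per: int = RATE_PER) -> float:
    """Fracture rate per ``per`` inhabitants, unrounded.

    Display rounding (2 decimals by convention) is handled separately.
    """
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / population * per


def expected_count(rate: float, population: float, per: int = RATE_PER) -> int:
    """Expected fracture count when ``rate`` (per ``per``) applies to ``population``.

    Rounded half-away-from-zero to an integer; stratum values are summed for
    totals (round-then-sum).
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return int(round_half_away(rate * population / per))


def excess_count(observed_ey: float, expected_ey: float) -> float:
    """Observed minus expected end-year count (may be negative)."""
    if observed_ey < 0 or expected_ey < 0:
        raise ValueError("counts must be >= 0")
    return observed_ey - expected_ey


def poisson_interval(
    mean: float, level: float = 0.95, method: str = "exact"
) -> UncertaintyBounds:
    """Confidence interval for a Poisson mean, clipped at 0.

    ``normal``: mean +/- z*sqrt(mean). ``exact``: Garwood inversion of the
    Poisson tail probabilities via the chi-square quantile identity.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if mean < 0:
        raise ValueError(f"mean must be >= 0, got {mean}")
    alpha = 1.0 - level
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(mean)
        return UncertaintyBounds(
            low=max(0.0, mean - half), high=max(0.0, mean + half), source="ci95"
        )
    if method == "exact":
        low = 0.0 if mean == 0 else stats.chi2.ppf(alpha / 2.0, 2.0 * mean) / 2.0
        high = stats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * mean + 2.0) / 2.0
        return UncertaintyBounds(low=low, high=high, source="ci95")
    raise ValueError(f"unknown interval method {method!r}")


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    pvalue: float


def goodness_of_fit(observed: list[float], expected: list[float]) -> GofResult:
    """Chi-square goodness of fit of observed vs expected counts across cells.

    chi2 = sum (O - E)^2 / E, df = cells - 1, upper-tail p-value.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected must have the same length")
    if len(observed) < 2:
        raise ValueError("goodness of fit needs at least two cells")
    if any(e <= 0 for e in expected):
        raise ValueError("expected cell counts must be > 0")
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = len(observed) - 1
    return GofResult(chi2=chi2, df=df, pvalue=float(stats.chi2.sf(chi2, df)))


@dataclass(frozen=True)
class StratumExpectation:
    sex: str
    rate_by: float  # per 10,000 (override or recomputed), unrounded
    rate_ey: float  # per 10,000, unrounded
    expected_ey: int
    excess: float
    interval_ne: UncertaintyBounds


@dataclass(frozen=True)
class ExpectationResult:
    strata: list[StratumExpectation]
    total_expected: int
    total_observed: float
    total_excess: float
    gof: GofResult = field(default=None)  # type: ignore[assignment]

    def stratum(self, sex: str) -> StratumExpectation:
        for s in self.strata:
            if s.sex == sex:
                return s
        raise KeyError(sex)


def compute_expectation(scenario: Scenario) -> ExpectationResult:
    """Run the expectation stage for every stratum of a scenario.

    A stratum's baseline rate is its ``rate_by`` override when given, otherwise
    recomputed from observed baseline count and population.
    """
    opts = scenario.options
    rows: list[StratumExpectation] = []
    for s in scenario.strata:
        rate_by = (
            s.rate_by
            if s.rate_by is not None
            else incidence_rate(s.observed_by, s.pop_by)
        )
        rate_ey = incidence_rate(s.observed_ey, s.pop_ey)
        ne = expected_count(rate_by, s.pop_ey)
        rows.append(
            StratumExpectation(
                sex=s.sex,
                rate_by=rate_by,
                rate_ey=rate_ey,
                expected_ey=ne,
                excess=excess_count(s.observed_ey, ne),
                interval_ne=poisson_interval(
                    ne, level=opts.interval_level, method=opts.interval_method
                ),
            )
        )
    total_expected = sum(r.expected_ey for r in rows)
    total_observed = sum(s.observed_ey for s in scenario.strata)
    gof = None
    if len(rows) >= 2:
        gof = goodness_of_fit(
            [s.observed_ey for s in scenario.strata],
            [float(r.expected_ey) for r in rows],
        )
    return ExpectationResult(
        strata=rows,
        total_expected=total_expected,
        total_observed=total_observed,
        total_excess=excess_count(total_observed, total_expected),
        gof=gof,
    )
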