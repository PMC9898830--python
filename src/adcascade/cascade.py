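"""The screening-cascade cost framework.

An ad campaign yields diagnoses through a multiplicative cascade:

    clicks  =  duration x daily clicks
    tests   =  clicks x conversion rate (c)
    new diagnoses = tests x positivity (p)

so the expected cost per new diagnosis of a campaign with budget B is

    B / (clicks x c x p)

and the cost per test drops the positivity factor. The conversion rate
is the fraction of clickers who go on to take an HIV test (the study
uses the health-care industry average, 11%); the positivity rate is the
fraction of tests yielding a new diagnosis, known by age band and by US
Census region. Expected counts are real-valued expectations, never
integerized.

Per-stratum evaluation follows the convention that a stratum's point
click estimate is the arithmetic mean of the four printed low/high
daily-click estimates times the campaign duration, and its budget is
the midpoint of the two adjusted budgets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import UndefinedCostError, ValidationError
from .estimates_io import (
    AdEstimateRow,
    PositivityTable,
    RegionMap,
    StudyConstants,
)
from .money import display_cents


@dataclass(frozen=True)
class CascadeParams:
    """Epidemiological constants of the cascade for one stratum.

    conversion_rate
        Fraction of ad clickers who take a test, in (0, 1].
    positivity
        Fraction of tests that yield a new diagnosis, in [0, 1].
    duration
        Campaign length in days (>= 1).
    """

    conversion_rate: float
    positivity: float
    duration: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.conversion_rate <= 1.0):
            raise ValidationError(f"conversion_rate {self.conversion_rate} outside (0, 1]")
        if not (0.0 <= self.positivity <= 1.0):
            raise ValidationError(f"positivity {self.positivity} outside [0, 1]")
        if self.duration < 1:
            raise ValidationError(f"duration {self.duration} must be >= 1 day")


@dataclass(frozen=True)
class StratumResult:
    """Derived campaign economics for one stratum."""

    stratum_id: str
    potential_reach: float
    avg_budget: float
    total_clicks: float
    expected_tests: float
    expected_diagnoses: float
    cost_per_test: float
    cost_per_diagnosis: float
    cost_per_thousand_reach: float
    band_label: str | None = None


@dataclass(frozen=True)
class TableSummary:
    """Column totals of an evaluated estimate table."""

    n_strata: int
    total_potential_reach: float
    total_budget_low: float
    total_budget_high: float


def total_clicks(row: AdEstimateRow, duration: float) -> float:
    """Expected campaign clicks: duration x mean of the four daily-click estimates."""
    if duration < 1:
        raise ValidationError(f"duration {duration} must be >= 1 day")
    quad = row.click_quadruple
    return duration * (sum(quad) / 4.0)


def expected_tests(clicks: float, conversion_rate: float) -> float:
    """Expected HIV tests from a click total."""
    if clicks < 0:
        raise ValidationError(f"clicks {clicks} must be >= 0")
    return clicks * conversion_rate


def expected_diagnoses(tests: float, positivity: float) -> float:
    """Expected new diagnoses from an expected test count."""
    if tests < 0:
        raise ValidationError(f"tests {tests} must be >= 0")
    return tests * positivity


def cost_per_test(budget: float, clicks: float, conversion_rate: float) -> float:
    """Budget divided by expected tests; full precision."""
    yield_ = clicks * conversion_rate
    if yield_ <= 0:
        raise UndefinedCostError(
            f"expected tests is {yield_}; cost per test undefined (no detectable yield)"
        )
    return budget / yield_


def cost_per_diagnosis(budget: float, clicks: float, params: CascadeParams) -> float:
    """Budget divided by expected new diagnoses; full precision."""
    yield_ = clicks * params.conversion_rate * params.positivity
    if yield_ <= 0:
        raise UndefinedCostError(
            f"expected diagnoses is {yield_}; cost per diagnosis undefined "
            "(no detectable yield)"
        )
    return budget / yield_


def cost_per_thousand_reach(budget: float, reach: float) -> float:
    """Budget per 1000 persons of potential reach — the standard ad-efficiency metric."""
    if reach <= 0:
        raise UndefinedCostError(f"reach is {reach}; cost per 1000 reached undefined")
    return budget / (reach / 1000.0)


def fixed_price_cost_per_diagnosis(
    constants: StudyConstants, daily_clicks: float, params: CascadeParams
) -> float:
    """Cost per diagnosis of a unit-budget ad (e.g. one $10, 10-day ad).

    Closed form: unit_budget / (duration x daily_clicks x c x p). Running k
    identical unit ads multiplies budget and yield alike, so the figure is
    independent of how many unit ads a campaign comprises.
    """
    yield_ = params.duration * daily_clicks * params.conversion_rate * params.positivity
    if yield_ <= 0:
        raise UndefinedCostError(
            f"expected diagnoses per unit ad is {yield_}; cost undefined"
        )
    return constants.unit_ad_budget / yield_


def evaluate_stratum(row: AdEstimateRow, params: CascadeParams) -> StratumResult:
    """Full cascade economics for one estimate row.

    Budget is the midpoint of the two adjusted budgets; clicks are
    ``total_clicks`` over the campaign duration.
    """
    budget = row.avg_budget
    clicks = total_clicks(row, params.duration)
    tests = expected_tests(clicks, params.conversion_rate)
    diagnoses = expected_diagnoses(tests, params.positivity)
    return StratumResult(
        stratum_id=row.stratum_id,
        potential_reach=row.potential_reach,
        avg_budget=budget,
        total_clicks=clicks,
        expected_tests=tests,
        expected_diagnoses=diagnoses,
        cost_per_test=cost_per_test(budget, clicks, params.conversion_rate),
        cost_per_diagnosis=cost_per_diagnosis(budget, clicks, params),
        cost_per_thousand_reach=cost_per_thousand_reach(budget, row.potential_reach),
    )


def evaluate_table(
    rows: Sequence[AdEstimateRow],
    positivity: PositivityTable,
    region_map: RegionMap,
    constants: StudyConstants,
    *,
    band_width: float | None = None,
) -> tuple[list[StratumResult], TableSummary]:
    """Evaluate every state row with its Census region's positivity rate.

    Returns the per-stratum results (input order preserved) and a summary
    carrying the potential-reach and budget column totals. With
    ``band_width`` set, each result's ``band_label`` is filled from its
    cost per diagnosis.
    """
    results: list[StratumResult] = []
    for row in rows:
        region = region_map.region_of(row.stratum_id)
        params = CascadeParams(
            conversion_rate=constants.conversion_rate,
            positivity=positivity.positivity(region),
            duration=constants.duration,
        )
        res = evaluate_stratum(row, params)
        if band_width is not None:
            res = replace(res, band_label=assign_band(res.cost_per_diagnosis, band_width))
        results.append(res)
    summary = TableSummary(
        n_strata=len(rows),
        total_potential_reach=sum(r.potential_reach for r in rows),
        total_budget_low=sum(r.budget_low for r in rows),
        total_budget_high=sum(r.budget_high for r in rows),
    )
    return results, summary


def assign_band(value: float, band_width: float = 50.0) -> str:
    """Half-open currency band label, e.g. 243.02 at width 50 -> '200.00-249.99'.

    Band k covers [k*w, (k+1)*w); the label's upper edge displays as the
    band top minus one cent.
    """
    if value < 0:
        raise ValidationError(f"band value {value} must be >= 0")
    if band_width <= 0:
        raise ValidationError(f"band width {band_width} must be positive")
    k = math.floor(value / band_width + 1e-12)
    lo = k * band_width
    hi = (k + 1) * band_width - 0.01
    return f"{display_cents(lo):.2f}-{display_cents(hi):.2f}"


_RANKABLE = (
    "potential_reach",
    "avg_budget",
    "total_clicks",
    "expected_tests",
    "expected_diagnoses",
    "cost_per_test",
    "cost_per_diagnosis",
    "cost_per_thousand_reach",
)


def rank_strata(
    results: Iterable[StratumResult], key: str, direction: str = "desc"
) -> list[StratumResult]:
    """Stable sort of results by a numeric field; ties break alphabetically."""
    if key not in _RANKABLE:
        raise ValidationError(f"cannot rank by {key!r}; numeric fields are {_RANKABLE}")
    if direction not in ("asc", "desc"):
        raise ValidationError(f"direction must be 'asc' or 'desc', got {direction!r}")
    sign = -1.0 if direction == "desc" else 1.0
    return sorted(results, key=lambda r: (sign * getattr(r, key), r.stratum_id))
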