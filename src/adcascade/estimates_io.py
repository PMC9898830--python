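"""Typed data model and CSV I/O for ad-platform estimate tables.

The ad platform, given a target audience and a budget, returns *ranges*
(low/high) of estimated daily reach and daily link clicks. A campaign
table has one row per stratum (state, region, age band, or the whole
country) holding the audience's potential reach, two manually adjusted
budgets (tuned to the low and high ends of the estimated reach range),
and the four daily-reach and four daily-click estimates observed at
those two budgets.

This module defines the row types, the epidemiological-rate tables
(test positivity by age band and Census region), the state-to-region
map, and readers/writers for the packaged CSV fixtures.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    SchemaError,
    TableParseError,
    UnknownStratumError,
    ValidationError,
)
from .money import display_cents

STRATUM_KINDS = ("state", "region", "age_band", "national", "dependent_area")

ESTIMATE_COLUMNS = (
    "state",
    "potential_reach",
    "budget_low",
    "budget_high",
    "reach_ll",
    "reach_hl",
    "reach_lh",
    "reach_hh",
    "clicks_ll",
    "clicks_hl",
    "clicks_lh",
    "clicks_hh",
)


@dataclass(frozen=True)
class AdTargetSpec:
    """Identity of one targeting stratum (who the ad is aimed at)."""

    stratum_id: str
    stratum_kind: str = "state"
    age_low: int | None = None
    age_high: int | None = None

    def __post_init__(self):
        if self.stratum_kind not in STRATUM_KINDS:
            raise ValidationError(
                f"unknown stratum kind {self.stratum_kind!r}; expected one of {STRATUM_KINDS}"
            )
        if self.age_low is not None and self.age_high is not None and self.age_low > self.age_high:
            raise ValidationError(
                f"{self.stratum_id}: age_low {self.age_low} > age_high {self.age_high}"
            )


@dataclass(frozen=True)
class AdEstimateRow:
    """One stratum's platform estimates: reach, budgets, and the two
    low/high daily estimate pairs at the two adjusted budgets.

    Suffix convention for the quadruples: first letter = low/high end of
    the platform's estimate range, second = at the low/high budget
    (``daily_reach_low_at_high_budget`` etc.).
    """

    spec: AdTargetSpec
    potential_reach: float
    budget_low: float
    budget_high: float
    daily_reach_low_at_low_budget: float
    daily_reach_high_at_low_budget: float
    daily_reach_low_at_high_budget: float
    daily_reach_high_at_high_budget: float
    daily_clicks_low_at_low_budget: float
    daily_clicks_high_at_low_budget: float
    daily_clicks_low_at_high_budget: float
    daily_clicks_high_at_high_budget: float
    anomalies: tuple[str, ...] = ()

    def __post_init__(self):
        for f in fields(self):
            if f.name in ("spec", "anomalies"):
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{self.spec.stratum_id}: {f.name}={v} must be >= 0")
        if self.budget_low > self.budget_high:
            raise ValidationError(
                f"{self.spec.stratum_id}: budget_low {self.budget_low} > "
                f"budget_high {self.budget_high}"
            )

    @property
    def stratum_id(self) -> str:
        return self.spec.stratum_id

    @property
    def click_quadruple(self) -> tuple[float, float, float, float]:
        return (
            self.daily_clicks_low_at_low_budget,
            self.daily_clicks_high_at_low_budget,
            self.daily_clicks_low_at_high_budget,
            self.daily_clicks_high_at_high_budget,
        )

    @property
    def reach_quadruple(self) -> tuple[float, float, float, float]:
        return (
            self.daily_reach_low_at_low_budget,
            self.daily_reach_high_at_low_budget,
            self.daily_reach_low_at_high_budget,
            self.daily_reach_high_at_high_budget,
        )

    @property
    def avg_budget(self) -> float:
        return (self.budget_low + self.budget_high) / 2.0

    @property
    def flagged(self) -> bool:
        return bool(self.anomalies)


def _detect_anomalies(row: AdEstimateRow) -> tuple[str, ...]:
    """Flag estimate patterns that contradict the platform's contract.

    Two patterns are checked, for reach and clicks alike: the low end of
    an estimate range exceeding the high end at the same budget, and an
    estimate *shrinking* when the budget increases. Flagged rows are
    carried, not rejected: published tables contain such rows verbatim.
    """
    flags: list[str] = []
    for kind, quad in (("reach", row.reach_quadruple), ("clicks", row.click_quadruple)):
        ll, hl, lh, hh = quad
        if ll > hl:
            flags.append(f"{kind}: low estimate {ll} > high estimate {hl} at the low budget")
        if lh > hh:
            flags.append(f"{kind}: low estimate {lh} > high estimate {hh} at the high budget")
        if lh < ll:
            flags.append(f"{kind}: low estimate fell from {ll} to {lh} as budget rose")
        if hh < hl:
            flags.append(f"{kind}: high estimate fell from {hl} to {hh} as budget rose")
    return tuple(flags)


def _parse_number(cell: str, *, row_id: str, column: str) -> float:
    text = str(cell).strip().replace(",", "")
    try:
        return float(text)
    except ValueError:
        raise TableParseError(
            f"row {row_id!r}, column {column!r}: cannot parse {cell!r} as a number"
        ) from None


def read_estimate_table(path: str | Path, kind: str = "state") -> list[AdEstimateRow]:
    """Read an 11-column estimate table into validated rows.

    Thousands separators are stripped; rows whose estimates violate the
    low<=high / monotone-in-budget pattern load with ``anomalies`` set.
    Raises :class:`SchemaError` for missing columns, :class:`TableParseError`
    for non-numeric cells, :class:`ValidationError` for duplicate strata.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    rows: list[AdEstimateRow] = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        stratum_id = str(rec["state"]).strip()
        if stratum_id in seen:
            raise ValidationError(f"{path}: duplicate stratum {stratum_id!r}")
        seen.add(stratum_id)
        values = {
            col: _parse_number(rec[col], row_id=stratum_id, column=col)
            for col in ESTIMATE_COLUMNS[1:]
        }
        row = AdEstimateRow(
            spec=AdTargetSpec(stratum_id=stratum_id, stratum_kind=kind),
            potential_reach=values["potential_reach"],
            budget_low=values["budget_low"],
            budget_high=values["budget_high"],
            daily_reach_low_at_low_budget=values["reach_ll"],
            daily_reach_high_at_low_budget=values["reach_hl"],
            daily_reach_low_at_high_budget=values["reach_lh"],
            daily_reach_high_at_high_budget=values["reach_hh"],
            daily_clicks_low_at_low_budget=values["clicks_ll"],
            daily_clicks_high_at_low_budget=values["clicks_hl"],
            daily_clicks_low_at_high_budget=values["clicks_lh"],
            daily_clicks_high_at_high_budget=values["clicks_hh"],
        )
        row = replace(row, anomalies=_detect_anomalies(row))
        rows.append(row)
    return rows


def write_estimate_table(rows: Iterable[AdEstimateRow], path: str | Path) -> None:
    """Write rows back to the 11-column CSV layout (integers stay integral)."""

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ESTIMATE_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.stratum_id]
                + [
                    fmt(v)
                    for v in (
                        r.potential_reach,
                        r.budget_low,
                        r.budget_high,
                        *r.reach_quadruple,
                        *r.click_quadruple,
                    )
                ]
            )


@dataclass(frozen=True)
class PositivityTable:
    """Test positivity (fraction of tests yielding a new diagnosis) per stratum."""

    entries: Mapping[str, float]

    def __post_init__(self):
        for sid, p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"positivity for {sid!r} is {p}, outside [0, 1]")

    def positivity(self, stratum_id: str) -> float:
        try:
            return self.entries[stratum_id]
        except KeyError:
            raise UnknownStratumError(
                f"no positivity entry for stratum {stratum_id!r}"
            ) from None


def read_positivity_table(path: str | Path) -> PositivityTable:
    """Load a positivity CSV (percent on disk, fraction in memory)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    for col in ("stratum_id", "positivity_pct"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    entries: dict[str, float] = {}
    for _, rec in df.iterrows():
        sid = str(rec["stratum_id"]).strip()
        if sid in entries:
            raise ValidationError(f"{path}: duplicate stratum {sid!r}")
        entries[sid] = _parse_number(rec["positivity_pct"], row_id=sid, column="positivity_pct") / 100.0
    return PositivityTable(entries=entries)


@dataclass(frozen=True)
class StudyConstants:
    """Campaign-level constants: click-to-test conversion, duration, unit ad budget."""

    conversion_rate: float = 0.11
    duration: float = 10.0
    unit_ad_budget: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.conversion_rate <= 1.0):
            raise ValidationError(f"conversion_rate {self.conversion_rate} outside (0, 1]")
        if self.duration < 1:
            raise ValidationError(f"duration {self.duration} must be >= 1 day")
        if self.unit_ad_budget <= 0:
            raise ValidationError(f"unit_ad_budget {self.unit_ad_budget} must be positive")


N_US_STATES = 50
DEPENDENT_AREAS = ("Puerto Rico", "US Virgin Islands")
DEPENDENT_REGION = "US dependent areas"


@dataclass(frozen=True)
class RegionMap:
    """State -> Census-region mapping (plus the two dependent areas)."""

    entries: Mapping[str, str]

    def region_of(self, state: str) -> str:
        try:
            return self.entries[state.strip()]
        except KeyError:
            raise UnknownStratumError(f"state {state!r} not present in the region map") from None

    def validate_complete(self) -> None:
        """Assert full coverage: 50 states, each in exactly one region, plus
        Puerto Rico and the US Virgin Islands under the dependent-areas label."""
        states = [s for s in self.entries if s not in DEPENDENT_AREAS]
        if len(states) != N_US_STATES:
            raise ValidationError(
                f"region map covers {len(states)} states; expected {N_US_STATES}"
            )
        for area in DEPENDENT_AREAS:
            if self.entries.get(area) != DEPENDENT_REGION:
                raise ValidationError(f"{area!r} must map to {DEPENDENT_REGION!r}")


def region_of(state: str, region_map: RegionMap) -> str:
    """Census region of a state (function form of :meth:`RegionMap.region_of`)."""
    return region_map.region_of(state)


def read_region_map(path: str | Path, *, require_complete: bool = True) -> RegionMap:
    df = pd.read_csv(path, dtype=str, comment="#")
    for col in ("state", "region"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    entries: dict[str, str] = {}
    for _, rec in df.iterrows():
        state = str(rec["state"]).strip()
        if state in entries:
            raise ValidationError(f"{path}: state {state!r} appears in two regions")
        entries[state] = str(rec["region"]).strip()
    rmap = RegionMap(entries=entries)
    if require_complete:
        rmap.validate_complete()
    return rmap


# ---------------------------------------------------------------------------
# StratumResult persistence

RESULT_COLUMNS = (
    "stratum_id",
    "potential_reach",
    "avg_budget",
    "total_clicks",
    "expected_tests",
    "expected_diagnoses",
    "cost_per_test",
    "cost_per_diagnosis",
    "cost_per_thousand_reach",
    "band_label",
)
_DISPLAY_COLUMNS = (
    "avg_budget",
    "cost_per_test",
    "cost_per_diagnosis",
    "cost_per_thousand_reach",
)


def write_results(results, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write stratum results as CSV: full-precision columns (``repr`` round-trip)
    plus 2-decimal ``*_display`` columns for the monetary fields."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(list(RESULT_COLUMNS) + [f"{c}_display" for c in _DISPLAY_COLUMNS])
        for r in results:
            base = [
                r.stratum_id,
                *(repr(float(getattr(r, c))) for c in RESULT_COLUMNS[1:-1]),
                r.band_label or "",
            ]
            writer.writerow(base + [f"{display_cents(getattr(r, c)):.2f}" for c in _DISPLAY_COLUMNS])


def read_results(path: str | Path) -> list:
    """Reload a results CSV written by :func:`write_results`."""
    from .cascade import StratumResult  # local import to avoid a cycle

    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out = []
    for _, rec in df.iterrows():
        band = rec["band_label"]
        out.append(
            StratumResult(
                stratum_id=str(rec["stratum_id"]),
                band_label=None if pd.isna(band) or band == "" else str(band),
                **{c: float(rec[c]) for c in RESULT_COLUMNS[1:-1]},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures

_FIXTURES = (
    "table2_states.csv",
    "table2_national.csv",
    "table3_positivity.csv",
    "census_regions.csv",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged CSV fixture."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    return Path(resources.files("adcascade.data") / name)


def load_packaged_study():
    """Load the packaged study inputs.

    Returns ``(state_rows, national_row, positivity, region_map)``:
    the 50-state estimate table, the single all-US row, the positivity
    table by age band / region (fractions), and the Census region map.
    """
    states = read_estimate_table(fixture_path("table2_states.csv"), kind="state")
    national = read_estimate_table(fixture_path("table2_national.csv"), kind="national")[0]
    positivity = read_positivity_table(fixture_path("table3_positivity.csv"))
    region_map = read_region_map(fixture_path("census_regions.csv"))
    return states, national, positivity, region_map
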