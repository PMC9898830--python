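"""Synthetic ad-platform estimate generator.

Stands in for the advertising platform so the whole pipeline is testable
offline: given a set of strata (audiences with a potential reach and a
region), it produces estimate rows with the statistical structure the
analysis assumes — a saturating exponential-CDF budget response, low/high
estimate bands around the point estimate, per-stratum heterogeneity, and
reproducible multiplicative noise.

The saturation scale is proportional to audience size: a stratum with
potential reach N saturates at beta_reach x (N / reference_reach)
dollars, so the budget needed to reach a fixed fraction of the audience
scales linearly with the audience — the pattern real per-state budget
tables show. Defaults are calibrated so that a 430,000-person audience
needs roughly a $12,000 10-day budget to reach 10% of it per day, with
clicks about 2% of reach and estimate bands of +/-50%.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .budget_response import BudgetSweep, ResponseCurve, fit_response, required_budget
from .errors import FittingError, ValidationError
from .estimates_io import AdEstimateRow, AdTargetSpec, StudyConstants


@dataclass(frozen=True)
class SyntheticStratum:
    """One synthetic audience: identifier, potential reach, Census region."""

    stratum_id: str
    potential_reach: float
    region: str

    def __post_init__(self):
        if self.potential_reach <= 0:
            raise ValidationError(f"{self.stratum_id}: potential_reach must be positive")


@dataclass(frozen=True)
class PlatformParams:
    """Generative parameters of the synthetic platform.

    beta_reach
        Saturation scale (USD) of the daily-reach curve for an audience of
        ``reference_reach`` persons; other strata scale proportionally.
    click_fraction
        Daily clicks as a proportion of daily reach at the same budget.
    range_width
        Half-width of the low/high estimate band, as a fraction of the
        point estimate (low, high = point x (1 -/+ range_width)).
    noise_sd
        Sigma of multiplicative log-normal noise applied to point
        estimates before banding; 0 gives a fully deterministic platform.
    """

    strata: Sequence[SyntheticStratum] = ()
    beta_reach: float = 118_000.0
    reference_reach: float = 430_000.0
    click_fraction: float = 0.02
    range_width: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.beta_reach <= 0 or self.reference_reach <= 0:
            raise ValidationError("beta_reach and reference_reach must be positive")
        if not (0.0 < self.click_fraction < 1.0):
            raise ValidationError(f"click_fraction {self.click_fraction} outside (0, 1)")
        if self.range_width < 0 or self.range_width >= 1.0:
            raise ValidationError(f"range_width {self.range_width} outside [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd {self.noise_sd} must be >= 0")

    def curve_for(self, stratum: SyntheticStratum) -> ResponseCurve:
        """Daily-reach response curve of one stratum (asymptote = its audience)."""
        beta = self.beta_reach * stratum.potential_reach / self.reference_reach
        return ResponseCurve(r_max=stratum.potential_reach, beta=beta)


@dataclass(frozen=True)
class EstimateBand:
    """The platform's answer at one budget: daily reach and clicks, low/high."""

    reach_low: float
    reach_high: float
    clicks_low: float
    clicks_high: float


def generate_estimate(
    stratum: SyntheticStratum,
    budget: float,
    params: PlatformParams,
    rng: np.random.Generator,
) -> EstimateBand:
    """Daily reach/click estimate band for one stratum at one budget.

    The point estimate is the stratum's curve value perturbed by
    log-normal noise (one independent factor each for reach and clicks);
    the band is the point times (1 -/+ range_width). Reproducible given
    the generator state.
    """
    if budget <= 0:
        raise ValidationError(f"budget {budget} must be positive")
    curve = params.curve_for(stratum)
    point_reach = float(curve.response(budget))
    point_clicks = params.click_fraction * point_reach
    if params.noise_sd > 0:
        point_reach *= float(np.exp(rng.normal(0.0, params.noise_sd)))
        point_clicks *= float(np.exp(rng.normal(0.0, params.noise_sd)))
    w = params.range_width
    return EstimateBand(
        reach_low=point_reach * (1 - w),
        reach_high=point_reach * (1 + w),
        clicks_low=point_clicks * (1 - w),
        clicks_high=point_clicks * (1 + w),
    )


def generate_state_table(
    params: PlatformParams, constants: StudyConstants
) -> list[AdEstimateRow]:
    """Emulate the construction of a per-stratum estimate table.

    For each stratum the two adjusted budgets are found by inverting the
    response curve at the high and low ends of the estimate band (a more
    optimistic platform needs less money), targeting 1/duration of the
    audience per day so the campaign covers the full potential reach;
    budgets round up to the unit ad budget. The platform is then queried
    at both budgets for the daily reach/click bands. Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    fraction = 1.0 / constants.duration
    rows: list[AdEstimateRow] = []
    for stratum in params.strata:
        base = params.curve_for(stratum)
        w = params.range_width
        optimistic = ResponseCurve(r_max=base.r_max * (1 + w), beta=base.beta)
        pessimistic = ResponseCurve(r_max=base.r_max * (1 - w), beta=base.beta)
        budget_low = required_budget(
            optimistic,
            stratum.potential_reach,
            constants.duration,
            fraction_per_day=fraction,
            rounding_unit=constants.unit_ad_budget,
        )
        budget_high = required_budget(
            pessimistic,
            stratum.potential_reach,
            constants.duration,
            fraction_per_day=fraction,
            rounding_unit=constants.unit_ad_budget,
        )
        at_low = generate_estimate(stratum, budget_low, params, rng)
        at_high = generate_estimate(stratum, budget_high, params, rng)
        rows.append(
            AdEstimateRow(
                spec=AdTargetSpec(stratum_id=stratum.stratum_id, stratum_kind="state"),
                potential_reach=stratum.potential_reach,
                budget_low=budget_low,
                budget_high=budget_high,
                daily_reach_low_at_low_budget=at_low.reach_low,
                daily_reach_high_at_low_budget=at_low.reach_high,
                daily_reach_low_at_high_budget=at_high.reach_low,
                daily_reach_high_at_high_budget=at_high.reach_high,
                daily_clicks_low_at_low_budget=at_low.clicks_low,
                daily_clicks_high_at_low_budget=at_low.clicks_high,
                daily_clicks_low_at_high_budget=at_high.clicks_low,
                daily_clicks_high_at_high_budget=at_high.clicks_high,
            )
        )
    return rows


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery diagnostics for the response-curve fitter."""

    n_replicates: int
    n_failed: int
    beta_rel_errors: tuple[float, ...]
    r_max_rel_errors: tuple[float, ...]

    @property
    def median_beta_rel_error(self) -> float:
        return statistics.median(self.beta_rel_errors)

    @property
    def median_r_max_rel_error(self) -> float:
        return statistics.median(self.r_max_rel_errors)


def recovery_experiment(
    true_curve: ResponseCurve,
    n_budgets: int,
    noise_sd: float,
    seed: int,
    *,
    n_replicates: int = 1,
    budget_range: tuple[float, float] = (10.0, 1_000_000.0),
) -> RecoveryReport:
    """Generate budget sweeps from a known curve, refit, report errors.

    Budgets are log-spaced over ``budget_range``; responses carry
    multiplicative log-normal noise of the given sigma. Fitting failures
    are counted, not raised. With noise_sd=0 recovery is exact to solver
    tolerance.
    """
    if n_budgets < 5:
        raise ValidationError(f"n_budgets {n_budgets} must be >= 5")
    budgets = np.geomspace(budget_range[0], budget_range[1], n_budgets)
    truth = np.asarray(true_curve.response(budgets), dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    beta_errs: list[float] = []
    rmax_errs: list[float] = []
    n_failed = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_budgets)) if noise_sd > 0 else 1.0
        sweep = BudgetSweep(
            observations=list(zip(budgets.tolist(), (truth * noise).tolist())),
            response_kind="daily_reach",
        )
        try:
            fit = fit_response(sweep)
        except FittingError:
            n_failed += 1
            continue
        beta_errs.append(abs(fit.curve.beta / true_curve.beta - 1.0))
        rmax_errs.append(abs(fit.curve.r_max / true_curve.r_max - 1.0))
    if not beta_errs:
        raise FittingError("every replicate failed to fit")
    return RecoveryReport(
        n_replicates=n_replicates,
        n_failed=n_failed,
        beta_rel_errors=tuple(beta_errs),
        r_max_rel_errors=tuple(rmax_errs),
    )
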