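"""Saturating budget-response curves and ad-strategy comparison.

Empirically, an ad's daily reach and daily clicks rise with budget but
saturate: the observed shape is the cumulative distribution function of
an exponential,

    f(B) = r_max * (1 - exp(-B / beta)),

with ``r_max`` the asymptotic daily response and ``beta`` the dollar
scale of saturation. The curve is strictly increasing and strictly
concave, which is why splitting a budget across many small ads (each
starting back in the steep region of its own curve) yields at least as
many clicks as one large ad: k * f(B/k) >= f(B) for every k >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .cascade import CascadeParams, cost_per_diagnosis
from .errors import FittingError, InfeasibleTargetError, UndefinedCostError, ValidationError


@dataclass(frozen=True)
class ResponseCurve:
    """Exponential-saturation response curve f(B) = r_max (1 - e^(-B/beta))."""

    r_max: float
    beta: float

    def __post_init__(self):
        if not (self.r_max > 0 and math.isfinite(self.r_max)):
            raise ValidationError(f"r_max {self.r_max} must be positive and finite")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValidationError(f"beta {self.beta} must be positive and finite")

    def response(self, budget) -> float:
        """Expected daily response at the given budget."""
        return self.r_max * -np.expm1(-np.asarray(budget, dtype=float) / self.beta)

    def __call__(self, budget) -> float:
        return self.response(budget)


@dataclass(frozen=True)
class BudgetSweep:
    """Budget sweep observations for one audience: (budget, daily response)."""

    observations: Sequence[tuple[float, float]]
    response_kind: str = "daily_clicks"  # or "daily_reach"

    def __post_init__(self):
        if self.response_kind not in ("daily_reach", "daily_clicks"):
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")
        budgets = [b for b, _ in self.observations]
        if any(b <= 0 for b in budgets):
            raise ValidationError("all sweep budgets must be strictly positive")
        if len(set(budgets)) != len(budgets):
            raise ValidationError("sweep budgets must be distinct")
        if any(r < 0 for _, r in self.observations):
            raise ValidationError("sweep responses must be >= 0")

    @property
    def budgets(self) -> np.ndarray:
        return np.array([b for b, _ in self.observations], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.observations], dtype=float)


@dataclass(frozen=True)
class FitResult:
    """A fitted curve plus convergence diagnostics."""

    curve: ResponseCurve
    residual_norm: float
    n_evaluations: int
    converged: bool


def fit_response(sweep: BudgetSweep, *, max_nfev: int = 2000) -> FitResult:
    """Least-squares fit of (r_max, beta) to a budget sweep.

    Parameters are optimized in log space (positivity for free); beta is
    initialized by a secant through the origin from the smallest-budget
    observation (where the curve is near-linear with slope r_max/beta)
    and r_max at 1.05x the largest observed response. Raises
    :class:`FittingError` (carrying the best iterate) on non-convergence
    or degenerate sweeps.
    """
    b = sweep.budgets
    y = sweep.responses
    if len(b) < 3:
        raise ValidationError("fit_response needs at least 3 observations")
    y_max = float(y.max())
    if y_max <= 0:
        raise FittingError("all responses are zero; the curve is unidentifiable")
    if float(y.min()) == y_max:
        raise FittingError("all responses equal; no curvature to fit")
    if not np.any(y < 0.95 * y_max):
        raise FittingError(
            "every observation sits in the saturated regime; beta is unidentifiable"
        )

    order = np.argsort(b)
    b_small, y_small = b[order[0]], y[order[0]]
    r0 = 1.05 * y_max
    slope0 = y_small / b_small if y_small > 0 else y_max / b[order[len(b) // 2]]
    beta0 = max(r0 / slope0, 1e-9)

    def residuals(theta):
        r_max, beta = np.exp(theta)
        return r_max * -np.expm1(-b / beta) - y

    sol = least_squares(residuals, x0=np.log([r0, beta0]), max_nfev=max_nfev)
    curve = ResponseCurve(r_max=float(np.exp(sol.x[0])), beta=float(np.exp(sol.x[1])))
    result = FitResult(
        curve=curve,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_evaluations=int(sol.nfev),
        converged=bool(sol.success),
    )
    if not sol.success:
        raise FittingError(
            f"fit did not converge after {sol.nfev} evaluations "
            f"(residual norm {result.residual_norm:.3g})",
            best=result,
        )
    return result


def marginal_response(curve: ResponseCurve, budget: float) -> float:
    """Response gained per extra dollar: f'(B) = (r_max/beta) e^(-B/beta).

    Strictly decreasing in budget — every additional dollar buys less.
    """
    if budget < 0:
        raise ValidationError(f"budget {budget} must be >= 0")
    return (curve.r_max / curve.beta) * math.exp(-budget / curve.beta)


def required_budget(
    curve: ResponseCurve,
    potential_reach: float,
    duration: float,
    fraction_per_day: float = 0.1,
    rounding_unit: float = 10.0,
) -> float:
    """Smallest budget whose daily response covers a fraction of the audience.

    Inverts the curve at target = fraction_per_day * potential_reach:
    B = -beta ln(1 - target/r_max), then rounds up to the nearest
    ``rounding_unit`` with a floor of one unit. A target at or above
    r_max is unattainable and raises :class:`InfeasibleTargetError`.
    """
    if duration < 1:
        raise ValidationError(f"duration {duration} must be >= 1 day")
    if rounding_unit <= 0:
        raise ValidationError(f"rounding_unit {rounding_unit} must be positive")
    target = fraction_per_day * potential_reach
    if target < 0:
        raise ValidationError(f"target {target} must be >= 0")
    if target >= curve.r_max:
        raise InfeasibleTargetError(
            f"daily target {target} is at or above the curve asymptote {curve.r_max}"
        )
    raw = -curve.beta * math.log1p(-target / curve.r_max)
    units = max(1, math.ceil(raw / rounding_unit - 1e-12))
    return units * rounding_unit


@dataclass(frozen=True)
class StrategyComparison:
    """One large ad vs many unit-budget ads over the same total spend.

    ``cost_per_diagnosis_*`` is None for an arm whose expected yield is
    zero (cost undefined there, the other arm still reported).
    """

    total_budget: float
    n_small_ads: int
    unit_budget: float
    clicks_single: float
    clicks_split: float
    cost_per_diagnosis_single: float | None
    cost_per_diagnosis_split: float | None
    audience_cap: float | None = None

    @property
    def split_advantage(self) -> float:
        """clicks_split / clicks_single (>= 1 whenever no cap binds)."""
        return self.clicks_split / self.clicks_single


def compare_strategies(
    curve: ResponseCurve,
    total_budget: float,
    unit_budget: float,
    params: CascadeParams,
    audience_cap: float | None = None,
) -> StrategyComparison:
    """Compare one ad of ``total_budget`` against many ads of ``unit_budget``.

    Each small ad is modelled as facing an identical, independent copy of
    the response curve, so the split arm earns n x duration x f(unit)
    clicks, optionally capped by ``audience_cap`` (total clicks the
    audience can supply over the campaign). Costs come from the cascade
    with the stratum's conversion and positivity rates.
    """
    if total_budget <= 0 or unit_budget <= 0:
        raise ValidationError("budgets must be positive")
    n = round(total_budget / unit_budget)
    if n < 1 or abs(n * unit_budget - total_budget) > 1e-6 * max(1.0, total_budget):
        raise ValidationError(
            f"unit budget {unit_budget} does not divide total budget {total_budget}"
        )
    clicks_single = params.duration * float(curve.response(total_budget))
    clicks_split = n * params.duration * float(curve.response(unit_budget))
    if audience_cap is not None:
        clicks_split = min(clicks_split, audience_cap)
        clicks_single = min(clicks_single, audience_cap)

    def arm_cost(clicks: float) -> float | None:
        try:
            return cost_per_diagnosis(total_budget, clicks, params)
        except UndefinedCostError:
            return None

    return StrategyComparison(
        total_budget=total_budget,
        n_small_ads=n,
        unit_budget=unit_budget,
        clicks_single=clicks_single,
        clicks_split=clicks_split,
        cost_per_diagnosis_single=arm_cost(clicks_single),
        cost_per_diagnosis_split=arm_cost(clicks_split),
        audience_cap=audience_cap,
    )
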