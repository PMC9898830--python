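"""Shared helpers for the analysis drivers."""

import math

from scipy.optimize import brentq

import adcascade as ac

# Observed anchors for the national all-age click response:
# a $10 ten-day ad averages ~28 clicks/day, while a single ad at the
# ~$61,000 national budget yields ~3.2 clicks/day per $10 of budget.
SMALL_AD_BUDGET = 10.0
SMALL_AD_DAILY_CLICKS = 28.0
NATIONAL_BUDGET = 61_030.0
NATIONAL_DAILY_CLICKS_PER_10 = 3.2


def calibrated_national_curve() -> ac.ResponseCurve:
    """Solve r_max (1 - e^(-B/beta)) through the two click anchors.

    Near the origin the curve's slope is r_max/beta = small-ad clicks per
    dollar; the saturation ratio at the national budget pins down
    B/beta, hence both parameters.
    """
    slope0 = SMALL_AD_DAILY_CLICKS / SMALL_AD_BUDGET
    national_slope = NATIONAL_DAILY_CLICKS_PER_10 / 10.0
    ratio = national_slope / slope0  # (1 - e^-x)/x at x = B/beta, decreasing in x
    x = brentq(lambda t: (1 - math.exp(-t)) / t - ratio, 1e-6, 50.0)
    beta = NATIONAL_BUDGET / x
    return ac.ResponseCurve(r_max=slope0 * beta, beta=beta)
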