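# Methods

## The model

`adcascade` estimates what a targeted social-media advertising campaign
costs per new HIV diagnosis. The campaign is modelled as a multiplicative
screening cascade: an ad with budget *B* running for *D* days earns an
expected number of link clicks; a fraction *c* of clickers take an HIV
test (the click-to-test **conversion rate**); a fraction *p* of tests
yield a new diagnosis (the **positivity rate**, known by age band and by
US Census region). The economics of one stratum are then

    clicks     = D x (daily clicks)
    tests      = clicks x c
    diagnoses  = tests x p
    cost per test       = B / (clicks x c)
    cost per diagnosis  = B / (clicks x c x p)
    cost per 1000 reach = B / (potential reach / 1000)

All expected counts are real-valued expectations — a campaign yielding
0.18 expected diagnoses is reported as such, never rounded to a draw.
When the expected yield is zero the per-outcome cost is *undefined*
(raised as `UndefinedCostError`), not infinite: it signals that no
detectable yield is possible under those parameters.

### Point-estimate conventions

The ad platform reports *ranges*: at each of two manually adjusted
budgets it gives a low and a high daily-reach and daily-click estimate.
The package's stratum convention is

- **clicks**: the arithmetic mean of the four printed daily-click
  estimates, times the campaign duration;
- **budget**: the midpoint of the two adjusted budgets;
- **positivity of a state**: the rate of its Census region (rates are
  published regionally, not per state).

These conventions reproduce the published per-state figures to the cent
(California $610.60, Washington $547.99, Utah $515.02, New Jersey
$508.03, and the national $257.51 / $18.50 pair).

Unit-ad ("fixed-price") costs use the closed form
`unit_budget / (D x daily_clicks x c x p)`, which is independent of how
many identical unit ads a campaign comprises. Daily-click point
estimates for age bands and regions are accepted as explicit inputs:
the platform prints some of them only as ranges (e.g. 31–33), and no
single bound/midpoint rule is consistent across strata, so the package
does not impose one.

### Defaults and units

| parameter | default | units | why |
|---|---|---|---|
| conversion rate *c* | 0.11 | fraction | health-care industry average click-to-action rate |
| duration *D* | 10 | days | the simulated campaign length |
| unit ad budget | 10 | USD | the smallest practical per-ad budget |
| band width | 50 | USD | granularity of the cost-per-diagnosis map bands |

Money is carried at full float precision; rounding to cents happens only
at display boundaries, ties away from zero (so 18.495 prints as 18.50).
Cost bands are half-open `[k·w, (k+1)·w)` with the label's upper edge
shown as the band top minus one cent (`200.00-249.99`).

## Budget-response saturation

Daily reach and clicks rise with budget but saturate, following the
cumulative distribution function of an exponential:

    f(B) = r_max (1 - exp(-B / beta))

with `r_max` the asymptotic daily response and `beta` the dollar scale
of saturation. This is the minimal two-parameter family with the
observed shape: f(0) = 0, strictly increasing, strictly concave,
f(B) -> r_max. Concavity implies k·f(B/k) >= f(B) for every k >= 1,
which is the whole economic argument for splitting a large budget into
many small ads: each unit ad restarts in the steep region of its own
curve. The split-strategy model assumes each small ad faces an
identical, independent copy of the curve, with total clicks optionally
capped by the audience size — without a cap the independent-ads model
would scale without bound.

**Fitting.** `fit_response` runs nonlinear least squares on the raw
scale with both parameters log-parameterized (positivity for free).
`beta` is initialized by a secant through the origin from the
smallest-budget observation (where f is near-linear with slope
r_max/beta) and `r_max` at 1.05x the largest observed response. A sweep
needs at least three distinct budgets and at least one observation below
95% of the maximum; otherwise `beta` is unidentifiable and fitting
raises rather than returning an arbitrary iterate. Noiseless sweeps are
recovered to solver tolerance (~1e-16 relative in practice) across four
orders of magnitude in beta; under 5% multiplicative noise with 50
log-spaced budgets the median relative error of beta over 20 replicates
is below 10% (about 3% in the packaged experiment).

**Budget inversion.** `required_budget` solves f(B) = target in closed
form, `B = -beta ln(1 - target/r_max)`, then rounds **up** to the
nearest rounding unit (ceiling, floor of one unit). The study's own
description of its procedure is ambiguous between nearest-and-up
rounding; ceiling is adopted because the procedure's narrative of what
was actually done says budgets were rounded up.

## The synthetic platform

`synthetic_platform` stands in for the ad platform so every pipeline
stage is testable offline. For each stratum (audience) it:

1. builds a daily-reach curve with `r_max` = the audience's potential
   reach and `beta` proportional to audience size
   (`beta_reach x reach / reference_reach`) — a shared absolute beta
   would make a 5,500-person and a 430,000-person audience saturate at
   the same dollar level, contradicting the budget-proportional-to-reach
   pattern of real per-state tables;
2. finds the two adjusted budgets by inverting the curve at the high
   and low edges of the estimate band (an optimistic platform needs less
   money), targeting 1/duration of the audience per day;
3. reports daily reach and clicks at both budgets, as symmetric bands
   `point x (1 -/+ range_width)` around a point estimate perturbed by
   multiplicative log-normal noise.

Defaults — `beta_reach` $118,000 at a reference reach of 430,000,
`click_fraction` 0.02, `range_width` 0.5, `noise_sd` 0.05 — are
calibrated once so a 430,000-person audience needs roughly a $12,000
ten-day budget to cover 10% of its reach per day, with clicks about 2%
of reach, matching the magnitudes of real state tables.

What the generator deliberately does **not** emulate: the platform's
delivery/auction dynamics, bid pacing, seasonality, 30-day active-user
accounting, or the asymmetric and opaque estimate bands real tables
show. Tests passing on synthetic data therefore validate the *algebra
and plumbing* of the pipeline — conservation, determinism, curve
recovery — not the realism of platform estimates themselves.

Determinism: all randomness flows through one `numpy` generator seeded
from `PlatformParams.seed`; identical parameters give byte-identical
CSV output.

## Data-fidelity choices

The packaged state table is transcribed verbatim from the published
table, including two rows whose daily-reach estimates *fall* as budget
rises (Illinois: 4,100 -> 1,200; Missouri: 5,400 -> 1,550). These are
carried as printed and loaded with an anomaly flag rather than
corrected or rejected — downstream sums use the printed values, and the
flag lets a user opt into fixing them. The 50-state potential-reach,
budget, reach and click columns all sum exactly to the published
totals, which is the transcription check.

State names are the join key (exact match after trimming). Thousands
separators are stripped on read; fixtures store bare integers.

## Reproduction pipeline

`pipeline.reproduce` evaluates the packaged tables end to end and emits
a machine-parseable check file: one row per published claim with the
computed display value, the printed value, and PASS/FAIL at
display-rounded equality (2 decimals for currency, exact for counts).
Every output CSV carries the run seed in a header comment and a sidecar
`run.json` records input checksums, so identical configurations produce
byte-identical outputs. One published column is *not* checked: the
"estimated positive tests" counts per age band and region, which depend
on per-stratum campaign budgets that were never published; their
generating formula (budget / cost per diagnosis) is implemented, but
its inputs cannot be recovered, so no claim is made.

## Problem sizes

Everything here is desk-scale: the state table has 50 rows, sweeps use
25–50 budget points, and the recovery experiment runs 20 replicate
fits. The full test suite and all analysis drivers complete in a few
seconds on one CPU.

## Known limitations

- The cascade is a chain of point expectations; no uncertainty
  intervals are propagated (the published figures are point estimates).
- The split-strategy model's independent-identical-ads assumption is
  optimistic at large ad counts; the audience cap is a blunt corrective.
- Positivity rates are 2017 surveillance values applied to 2021
  estimates; conversion is a cross-industry average. Both enter only as
  scalar multipliers, so any re-estimated rate can be substituted
  directly.
- Platform estimates are a black box and fluctuate day to day; the
  model inherits whatever bias they carry.
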