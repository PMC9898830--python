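#!/usr/bin/env python
"""Fit the saturating budget-response curve and validate parameter recovery.

The national-audience click response is calibrated to two observed
anchors (a $10 ten-day ad earns about 28 clicks/day; a single ad at the
~$61,000 national budget earns about 3.2 clicks/day per $10 of budget).
A budget sweep from $10 to $1,000,000 is generated from that curve —
noiseless and with 5% multiplicative noise — and refit, reporting how
well (r_max, beta) are recovered. Writes results/budget_response_fit.json.
"""

import json
from pathlib import Path

import numpy as np

import adcascade as ac
from analysis_common import calibrated_national_curve

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20210420


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    true_curve = calibrated_national_curve()
    print(
        f"calibrated national click curve: r_max={true_curve.r_max:,.0f} clicks/day, "
        f"beta=${true_curve.beta:,.0f}"
    )

    budgets = np.geomspace(10, 1_000_000, 25)
    sweep = ac.BudgetSweep(
        [(float(b), float(true_curve.response(b))) for b in budgets],
        response_kind="daily_clicks",
    )
    fit = ac.fit_response(sweep)
    print(
        f"noiseless refit: r_max={fit.curve.r_max:,.0f}, beta=${fit.curve.beta:,.0f} "
        f"(residual norm {fit.residual_norm:.2e})"
    )

    report = ac.recovery_experiment(
        true_curve, n_budgets=50, noise_sd=0.05, seed=SEED, n_replicates=20
    )
    print(
        f"5% noise, 20 replicates: median |beta error| "
        f"{report.median_beta_rel_error:.1%}, median |r_max error| "
        f"{report.median_r_max_rel_error:.1%}, {report.n_failed} failures"
    )

    payload = {
        "true": {"r_max": true_curve.r_max, "beta": true_curve.beta},
        "noiseless_fit": {
            "r_max": fit.curve.r_max,
            "beta": fit.curve.beta,
            "residual_norm": fit.residual_norm,
        },
        "noisy_recovery": {
            "n_replicates": report.n_replicates,
            "n_failed": report.n_failed,
            "median_beta_rel_error": report.median_beta_rel_error,
            "median_r_max_rel_error": report.median_r_max_rel_error,
        },
        "seed": SEED,
    }
    out = OUT / "budget_response_fit.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
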