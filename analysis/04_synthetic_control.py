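#!/usr/bin/env python
"""Recovery study for the ridge-augmented synthetic control.

On weekly-scale panels (15 donors, 40 pre-intervention and 12
post-intervention weeks) with a known 15% injected reduction, fits the
augmented synthetic control with Jackknife+ intervals across 50 seeds
and tabulates the estimated relative effect and interval coverage.
A matched null study (no injected effect) measures the false-positive
rate of the 3-month significance call.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aqcausal.ascm import WeeklyPanel, fit_ascm
from aqcausal.effects import average_effect, post_period_effect
from aqcausal.synth import simulate_weekly_panel

RESULTS = Path(__file__).resolve().parents[1] / "results"
INTERVENTION = pd.Timestamp("2019-04-08")


def main() -> None:
    rows = []
    covered = 0
    for seed in range(50):
        treated, donors, _ = simulate_weekly_panel(
            n_donors=15, n_pre=40, n_post=12, effect_size=0.15, seed=seed
        )
        fit = fit_ascm(
            WeeklyPanel(treated=treated, donors=donors, intervention=INTERVENTION)
        )
        s = post_period_effect(fit)
        lo, hi = s.percent_interval
        covered += lo <= -15.0 <= hi
        rows.append(
            {
                "seed": seed,
                "percent": round(s.percent, 3),
                "percent_lo": round(lo, 3),
                "percent_hi": round(hi, 3),
                "pre_rmse": round(fit.pre_rmse, 4),
                "lambda": round(fit.lam, 6),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "ascm_recovery.csv", index=False)
    print(
        "injected -15%: mean estimate {:.2f}% (sd {:.2f}), "
        "95% interval covers truth in {}/50 seeds".format(
            df["percent"].mean(), df["percent"].std(), covered
        )
    )

    significant = 0
    for seed in range(50):
        treated, donors, _ = simulate_weekly_panel(
            n_donors=15, n_pre=40, n_post=14, effect_size=0.0, seed=2000 + seed
        )
        fit = fit_ascm(
            WeeklyPanel(treated=treated, donors=donors, intervention=INTERVENTION)
        )
        significant += bool(average_effect(fit, 3).significant)
    print(f"null panels: 3-month effect significant in {significant}/50 seeds")


if __name__ == "__main__":
    main()
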