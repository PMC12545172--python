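# aqcausal

Causal evaluation of air-quality interventions from hourly monitoring
data: machine-learning **weather normalization** ("deweathering")
followed by a **ridge-augmented synthetic control** with Jackknife+
prediction intervals.

## The problem

Did a low-emission-zone-style policy actually lower NO2, NOx or PM2.5?
A before/after comparison is confounded twice over: weather moves
concentrations by tens of percent week to week, and urban pollution has
been trending downward everywhere regardless of any one policy.  The
approach implemented here addresses both.  First, a random forest
(300 trees, minimum node size 5) learns each site's hourly
concentration from nine meteorological variables plus four time proxies
(Unix time, day of year, day of week, hour of day); predicting with the
meteorology resampled from climatologically comparable hours — same
hour of day, within ±2 weeks of the date in every year of the record —
yields the concentration under "average" weather while preserving the
seasonal, weekly and diel emission structure.  Second, the
weather-normalized series, averaged to weeks, is compared against a
counterfactual synthesized from donor cities unaffected by the policy:

```
Ŷ₁T = Σⱼ ŵⱼˢᶜᵐ Y_jT + (X₁ − Σⱼ ŵⱼˢᶜᵐ Xⱼ)·η̂ᴿⁱᵈᵍᵉ = Σⱼ ŵⱼᵃᵘᵍ Y_jT
```

where ŵˢᶜᵐ are simplex-constrained synthetic-control weights fitted to
the pre-period, η̂ᴿⁱᵈᵍᵉ is a ridge outcome model across donors, and the
augmented weights ŵᵃᵘᵍ absorb both.  The weekly causal effect is
Y₁T − Ŷ₁T with a Jackknife+ 95% band over leave-one-donor-out refits,
and the windowed percentage change is
P = (C_wn − C_cf)/C_cf × 100 over 1/3/6/9/11 calendar months, always
excluding the two-week transition period after the policy date.

The package is aimed at researchers in environmental epidemiology and
policy evaluation.  It ships a synthetic multi-city panel generator
with known ground truth (emission component, injected step effect), so
the whole pipeline is testable without downloading monitoring data;
real data in the supported CSV dialect drop into the same interfaces.

## Worked example

Recover a known 15% injected reduction from weekly panels
(15 donor cities, 40 pre- and 12 post-intervention weeks):

```python
import pandas as pd
from aqcausal.ascm import WeeklyPanel, fit_ascm
from aqcausal.effects import post_period_effect
from aqcausal.synth import simulate_weekly_panel

treated, donors, truth = simulate_weekly_panel(
    n_donors=15, n_pre=40, n_post=12, effect_size=0.15, seed=0
)
panel = WeeklyPanel(treated=treated, donors=donors,
                    intervention=pd.Timestamp("2019-04-08"))
fit = fit_ascm(panel)                 # weights, lambda by CV, Jackknife+ band
s = post_period_effect(fit)
print(f"estimated effect {s.percent:+.1f}% "
      f"(95% band {s.percent_interval[0]:+.1f} to {s.percent_interval[1]:+.1f})")
```

```
estimated effect -15.1% (95% band -18.5 to -12.1)
```

The injected −15% lies inside the band.  Across 50 seeds
(`analysis/04_synthetic_control.py`) the mean estimate is −14.95%
(sd 0.87) with the band covering the truth in 50/50 seeds, and matched
null panels (no injected effect) are declared significant in 0/50.

The numbered scripts under `analysis/` walk the full hourly pipeline on
the default two-year scenario: `01_simulate_panel.py` writes the
synthetic panel, `02_quality_control.py` applies the >75%-hours-per-day
and >80%-valid-days filters, `03_deweather.py` trains the forest
(held-out r = 0.794) and recovers the true emission component from the
normalized series (r = 0.916), `04_synthetic_control.py` runs the
recovery and null studies above, and `05_policy_effects.py` reports
windowed effects, the traffic-increment cross-check and the peak-hour
sensitivity comparison.  A `aqcausal` command-line interface
(`simulate`, `qc`, `deweather`, `ascm`, `run-all`, `evaluate`) wraps
the same library for file-based runs.

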