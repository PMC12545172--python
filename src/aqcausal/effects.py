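"""Policy-effect summaries derived from augmented synthetic-control fits.

Converts weekly counterfactual fits into the quantities a policy
evaluation reports: average absolute and relative effects over 1/3/6/9/11
calendar-month windows (excluding the two-week transition period right
after the intervention), traffic increments (urban traffic minus urban
background), a placebo-in-time rerun at a pseudo-intervention date, and a
peak-hour (6-9 a.m.) sensitivity comparison.

The relative effect is the percentage change

    P = (C_wn - C_counterfactual) / C_counterfactual * 100,

negative values meaning the intervention lowered concentrations below
what they would otherwise have been.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .ascm import AscmFit, WeeklyPanel, fit_ascm

TRANSITION_WEEKS = 2  # post-intervention weeks 0 and 1 never contribute


def percent_change(c_wn: float, c_cf: float) -> float:
    """Percentage change of the weather-normalized mean vs counterfactual."""
    if c_cf <= 0:
        raise ValueError("counterfactual mean must be positive for a percentage")
    return (c_wn - c_cf) / c_cf * 100.0


@dataclass
class EffectSummary:
    """Windowed average policy effect with a propagated 95% band."""

    window_months: int
    c_wn: float  # mean weather-normalized concentration, ug m-3
    c_counterfactual: float  # mean counterfactual, ug m-3
    absolute_effect: float  # c_wn - c_counterfactual, ug m-3
    percent: float
    interval: tuple[float, float] | None  # band on the absolute effect
    percent_interval: tuple[float, float] | None
    included_weeks: list[int]
    excluded_weeks: list[int]

    @property
    def significant(self) -> bool | None:
        """True when the propagated 95% band excludes zero."""
        if self.interval is None:
            return None
        lo, hi = self.interval
        return bool(lo > 0 or hi < 0)

    def to_dict(self) -> dict:
        d = {
            "window_months": self.window_months,
            "c_wn": self.c_wn,
            "c_counterfactual": self.c_counterfactual,
            "absolute_effect": self.absolute_effect,
            "percent": self.percent,
            "significant": self.significant,
        }
        if self.interval is not None:
            d["effect_lo"], d["effect_hi"] = self.interval
            d["percent_lo"], d["percent_hi"] = self.percent_interval
        return d


def included_weeks_for_window(
    intervention: pd.Timestamp,
    window_months: int,
) -> list[int]:
    """Post weeks whose start lies in [intervention + 14 d, + `months`).

    Windows are calendar months (``DateOffset(months=...)``), not 30-day
    blocks; the first two post weeks form the transition period and are
    always excluded.  The weeks are enumerated from the calendar alone —
    callers must verify they are all covered by data.
    """
    intervention = pd.Timestamp(intervention)
    hi = intervention + pd.DateOffset(months=window_months)
    out = []
    wk = TRANSITION_WEEKS
    while intervention + pd.Timedelta(days=7 * wk) < hi:
        out.append(wk)
        wk += 1
    return out


def average_effect(
    fit: AscmFit,
    window_months: int,
    intervention: pd.Timestamp | None = None,
) -> EffectSummary:
    """Average absolute and relative effect over a post-policy window."""
    intervention = pd.Timestamp(
        intervention if intervention is not None else fit.panel.intervention
    )
    post = fit.counterfactual.index
    include = included_weeks_for_window(intervention, window_months)
    if not include:
        raise ValueError("window contains no usable post-intervention weeks")
    missing = [w for w in include if w not in post]
    if missing:
        raise ValueError(
            f"window extends beyond available data: needs week {max(missing)}, "
            f"last covered week is {int(post.max())}"
        )
    excluded = [int(w) for w in post if w not in include]
    y = fit.panel.treated.loc[include]
    cf = fit.counterfactual.loc[include]
    if y.isna().any() or cf.isna().any():
        raise ValueError("missing weekly values inside the evaluation window")
    c_wn = float(y.mean())
    c_cf = float(cf.mean())
    eff = c_wn - c_cf

    interval = percent_interval = None
    if fit.lower is not None:
        # Conservative propagation: average the weekly band ends.
        cf_lo = float(fit.lower.loc[include].mean())
        cf_hi = float(fit.upper.loc[include].mean())
        interval = (c_wn - cf_hi, c_wn - cf_lo)
        percent_interval = (
            interval[0] / c_cf * 100.0,
            interval[1] / c_cf * 100.0,
        )
    return EffectSummary(
        window_months=window_months,
        c_wn=c_wn,
        c_counterfactual=c_cf,
        absolute_effect=eff,
        percent=percent_change(c_wn, c_cf),
        interval=interval,
        percent_interval=percent_interval,
        included_weeks=include,
        excluded_weeks=excluded,
    )


def post_period_effect(fit: AscmFit) -> EffectSummary:
    """Average effect over all post weeks past the transition period."""
    post = fit.counterfactual.index
    include = [int(w) for w in post if w >= TRANSITION_WEEKS]
    if not include:
        raise ValueError("no post-transition weeks available")
    y = fit.panel.treated.loc[include]
    cf = fit.counterfactual.loc[include]
    c_wn, c_cf = float(y.mean()), float(cf.mean())
    interval = percent_interval = None
    if fit.lower is not None:
        cf_lo = float(fit.lower.loc[include].mean())
        cf_hi = float(fit.upper.loc[include].mean())
        interval = (c_wn - cf_hi, c_wn - cf_lo)
        percent_interval = (interval[0] / c_cf * 100.0, interval[1] / c_cf * 100.0)
    return EffectSummary(
        window_months=0,
        c_wn=c_wn,
        c_counterfactual=c_cf,
        absolute_effect=c_wn - c_cf,
        percent=percent_change(c_wn, c_cf),
        interval=interval,
        percent_interval=percent_interval,
        included_weeks=include,
        excluded_weeks=[int(w) for w in post if w not in include],
    )


# ---------------------------------------------------------------------------
# Traffic increments
# ---------------------------------------------------------------------------

@dataclass
class TrafficIncrement:
    """Urban-traffic minus urban-background group means, pre vs post."""

    pre_increment: float  # ug m-3
    post_increment: float
    change: float  # post - pre, ug m-3
    change_percent: float  # relative to the pre-window increment
    negative_increment_flag: bool

    def to_dict(self) -> dict:
        return {
            "pre_increment": self.pre_increment,
            "post_increment": self.post_increment,
            "change": self.change,
            "change_percent": self.change_percent,
        }


def traffic_increment(
    ut_series: pd.Series,
    ub_series: pd.Series,
    pre_window: tuple,
    post_window: tuple,
) -> TrafficIncrement:
    """Change in the traffic increment between two time windows.

    ``pre_window``/``post_window`` are (start, end) timestamp pairs (end
    exclusive) applied to both hourly group series; by convention the pre
    window matches the causal model's pre-fit span.
    """

    def window_mean(series: pd.Series, window: tuple) -> float:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        vals = series[(series.index >= lo) & (series.index < hi)].dropna()
        if len(vals) == 0:
            raise ValueError(f"no data in window {window}")
        return float(vals.mean())

    pre = window_mean(ut_series, pre_window) - window_mean(ub_series, pre_window)
    post = window_mean(ut_series, post_window) - window_mean(ub_series, post_window)
    change = post - pre
    pct = change / pre * 100.0 if pre != 0 else float("nan")
    return TrafficIncrement(
        pre_increment=pre,
        post_increment=post,
        change=change,
        change_percent=pct,
        negative_increment_flag=(pre < 0 or post < 0),
    )


# ---------------------------------------------------------------------------
# Placebo-in-time
# ---------------------------------------------------------------------------

def placebo_in_time(
    panel_builder: Callable[[pd.Timestamp], WeeklyPanel],
    pseudo_date: pd.Timestamp,
    true_intervention: pd.Timestamp,
    window_months: int = 3,
    alpha: float = 0.05,
) -> EffectSummary:
    """Rerun the estimator at a pseudo-intervention date.

    ``panel_builder`` must return a weekly panel anchored at the date it
    is given, using only data from before the true intervention (so no
    genuine effect can leak in).  A significant window-average effect at
    the pseudo date indicates a spurious signal (e.g. an anticipation
    response, or an unstable donor pool).
    """
    pseudo_date = pd.Timestamp(pseudo_date)
    true_intervention = pd.Timestamp(true_intervention)
    if pseudo_date >= true_intervention:
        raise ValueError("pseudo-intervention date must precede the true one")
    panel = panel_builder(pseudo_date)
    if len(panel.pre_weeks) < 8:
        raise ValueError("need at least 8 pre-period weeks before the pseudo date")
    fit = fit_ascm(panel, alpha=alpha)
    return average_effect(fit, window_months, intervention=pseudo_date)


# ---------------------------------------------------------------------------
# Peak-hour sensitivity
# ---------------------------------------------------------------------------

PEAK_HOURS = (6, 7, 8, 9)


def peak_hour_sensitivity(
    build_panel: Callable[[tuple | None], WeeklyPanel],
    window_months: int = 3,
    alpha: float | None = 0.05,
    peak_hours: tuple = PEAK_HOURS,
) -> dict:
    """Compare relative effects from all-hours vs peak-hours pipelines.

    ``build_panel(hours)`` must rebuild the weekly panel from hourly
    weather-normalized series restricted to the given hours of day (None
    meaning all 24).  Returns both window summaries and the absolute
    difference in percentage points.
    """
    all_fit = fit_ascm(build_panel(None), alpha=alpha)
    peak_fit = fit_ascm(build_panel(tuple(peak_hours)), alpha=alpha)
    p_all = average_effect(all_fit, window_months)
    p_peak = average_effect(peak_fit, window_months)
    return {
        "all_hours": p_all,
        "peak_hours": p_peak,
        "abs_difference_pp": abs(p_peak.percent - p_all.percent),
    }
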