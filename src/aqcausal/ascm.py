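"""Ridge-augmented synthetic control on weekly panels, with Jackknife+.

The treated unit's counterfactual at post-intervention week T is

    Yhat_1T = sum_j w_j^scm Y_jT + (X_1 - sum_j w_j^scm X_j) . eta_T

where w^scm are the classic synthetic-control weights (non-negative,
summing to one, minimizing the pre-period discrepancy ||X_1 - X w||^2)
and eta_T are ridge coefficients regressing the donors' week-T outcome on
their pre-period vectors.  The correction term removes residual
pre-period bias that the simplex-constrained weights cannot absorb.
Substituting the ridge solution shows the estimator is linear in donor
outcomes with augmented weights

    w^aug = w^scm + X (X'X + lambda I)^{-1} (X_1 - X' w^scm),

which may be negative and need not sum to one.  Uncertainty comes from a
Jackknife+ construction over donor units: each donor is left out in turn,
the model refit, and the leave-one-out counterfactuals +/- that donor's
pseudo-treated pre-fit residual are combined through the Jackknife+
order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

WEEK_HOURS = 168
WEEK_COMPLETENESS = 0.75  # a week needs >= 75% of its hourly slots


class InsufficientDonorsError(ValueError):
    """Raised when the donor pool is too small for the requested step."""


# ---------------------------------------------------------------------------
# Weekly panel construction
# ---------------------------------------------------------------------------

def to_weekly(
    series: pd.Series,
    intervention: pd.Timestamp,
    hours: tuple | None = None,
) -> pd.Series:
    """Average an hourly series into 7-day blocks anchored at `intervention`.

    Week k covers [intervention + 7k days, intervention + 7(k+1) days), so
    week 0 begins exactly at the policy start.  The weekly value is the
    mean over available hours; a week with fewer than 75% of its expected
    hourly slots present is set to missing.  ``hours`` optionally
    restricts the computation to a subset of hours of day (e.g. the
    6-9 a.m. peak), shrinking the expected slot count accordingly.
    """
    s = series.dropna()
    if hours is not None:
        s = s[s.index.hour.isin(hours)]
    if len(series) < WEEK_HOURS:
        raise ValueError("series shorter than one week")
    intervention = pd.Timestamp(intervention)
    delta = s.index - intervention
    week = np.floor(delta.total_seconds() / (7 * 24 * 3600)).astype(int)
    expected = WEEK_HOURS if hours is None else 7 * len(hours)
    grouped = s.groupby(week)
    mean = grouped.mean()
    count = grouped.count()
    mean[count < WEEK_COMPLETENESS * expected] = np.nan
    # Restrict to weeks fully inside the observed span.
    span_lo = int(np.ceil((series.index.min() - intervention).total_seconds() / (7 * 24 * 3600)))
    span_hi = int(np.floor(((series.index.max() + pd.Timedelta(hours=1)) - intervention).total_seconds() / (7 * 24 * 3600)))
    weeks = pd.RangeIndex(span_lo, span_hi)
    out = mean.reindex(weeks)
    out.index.name = "week"
    return out


@dataclass
class WeeklyPanel:
    """Treated and donor weekly outcomes around an intervention.

    Indexed by integer week relative to the intervention (week 0 starts
    at the intervention instant).  Pre-period weeks are those < 0.
    """

    treated: pd.Series
    donors: pd.DataFrame
    intervention: pd.Timestamp | None = None

    def __post_init__(self):
        if self.donors.shape[1] < 2:
            raise InsufficientDonorsError("need at least 2 donors")
        common = self.treated.index.intersection(self.donors.index)
        self.treated = self.treated.loc[common]
        self.donors = self.donors.loc[common]
        pre = common[common < 0]
        if len(pre) == 0:
            raise ValueError("panel has no pre-intervention weeks")
        block = pd.concat([self.treated.loc[pre], self.donors.loc[pre]], axis=1)
        if block.isna().any().any():
            raise ValueError(
                "missing pre-period weeks; screen donors / sites before fitting"
            )

    @property
    def pre_weeks(self) -> pd.Index:
        return self.treated.index[self.treated.index < 0]

    @property
    def post_weeks(self) -> pd.Index:
        return self.treated.index[self.treated.index >= 0]

    @property
    def donor_names(self) -> list[str]:
        return list(self.donors.columns)

    @property
    def x1(self) -> np.ndarray:
        """Treated pre-period vector (p,)."""
        return self.treated.loc[self.pre_weeks].to_numpy(dtype=float)

    @property
    def xd(self) -> np.ndarray:
        """Donor pre-period matrix (p, J)."""
        return self.donors.loc[self.pre_weeks].to_numpy(dtype=float)

    def drop_donor(self, name: str) -> "WeeklyPanel":
        return WeeklyPanel(
            treated=self.treated,
            donors=self.donors.drop(columns=[name]),
            intervention=self.intervention,
        )

    def pseudo_treated(self, name: str) -> "WeeklyPanel":
        """Panel in which donor `name` plays the treated unit."""
        return WeeklyPanel(
            treated=self.donors[name],
            donors=self.donors.drop(columns=[name]),
            intervention=self.intervention,
        )


# ---------------------------------------------------------------------------
# SCM weights (simplex-constrained least squares)
# ---------------------------------------------------------------------------

def fit_scm_weights(panel: WeeklyPanel, ridge_tiebreak: float = 1e-10) -> np.ndarray:
    """Simplex-constrained least-squares donor weights.

    Minimizes ||X_1 - X w||^2 over the probability simplex.  The
    sum-to-one constraint is folded in as a heavily weighted penalty row
    and the resulting non-negative least-squares problem is solved with
    the exact active-set NNLS algorithm; the weights are then
    renormalized so the constraint holds exactly.  A vanishing ridge term
    breaks ties toward the minimum-norm weight vector when several
    simplex points achieve the optimum.
    """
    x1, xd = panel.x1, panel.xd
    p, J = xd.shape
    scale = max(float(np.abs(xd).mean()), 1e-12)
    gamma = 1e6 * scale * np.sqrt(p)
    tie = np.sqrt(ridge_tiebreak) * scale
    A = np.vstack([xd, gamma * np.ones((1, J)), tie * np.eye(J)])
    b = np.concatenate([x1, [gamma], np.zeros(J)])
    w, _ = optimize.nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("SCM weight solver returned a zero vector")
    return w / total


def scm_objective(panel: WeeklyPanel, w: np.ndarray) -> float:
    """Pre-period sum of squared discrepancies at weights `w`."""
    r = panel.x1 - panel.xd @ w
    return float(r @ r)


# ---------------------------------------------------------------------------
# Ridge augmentation
# ---------------------------------------------------------------------------

def _ridge_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve the regularized normal equations, minimum-norm when singular."""
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A) @ b

def fit_ridge_coefficients(
    panel: WeeklyPanel, lam: float, post_week: int
) -> np.ndarray:
    """Ridge coefficients regressing donors' week-T outcome on X_j.

    eta = (X'X + lambda I)^{-1} X' y with X the (J, p) matrix of donor
    pre-period vectors and y the donors' outcomes at ``post_week``.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    X = panel.xd.T  # (J, p)
    y = panel.donors.loc[post_week].to_numpy(dtype=float)
    return _ridge_solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y)


def select_lambda(
    panel: WeeklyPanel,
    grid: np.ndarray | None = None,
) -> float:
    """Leave-one-donor-out CV choice of the ridge penalty.

    The grid is log-spaced over 1e-3..1e3 relative to the pre-period
    outcome variance; the score is the mean squared error of predicting
    each held-out donor's post-week outcomes from its pre-period vector.
    """
    X = panel.xd.T
    J, p = X.shape
    post = panel.post_weeks
    if len(post) == 0:
        post = panel.pre_weeks[-1:]
    Y = panel.donors.loc[post].to_numpy(dtype=float).T  # (J, n_post)
    if grid is None:
        scale = max(float(np.var(panel.xd)), 1e-8)
        grid = scale * np.logspace(-3, 3, 13)
    best_lam, best_score = float(grid[0]), np.inf
    eye = np.eye(p)
    for lam in grid:
        errs = []
        for j in range(J):
            mask = np.ones(J, dtype=bool)
            mask[j] = False
            Xtr, Ytr = X[mask], Y[mask]
            eta = _ridge_solve(Xtr.T @ Xtr + lam * eye, Xtr.T @ Ytr)
            errs.append(np.mean((Y[j] - X[j] @ eta) ** 2))
        score = float(np.mean(errs))
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


# ---------------------------------------------------------------------------
# Fit container and counterfactual prediction
# ---------------------------------------------------------------------------

@dataclass
class AscmFit:
    """A fitted augmented synthetic control."""

    panel: WeeklyPanel
    scm_weights: np.ndarray  # (J,), >= 0, sums to 1
    lam: float
    aug_weights: np.ndarray  # (J,), unconstrained
    counterfactual: pd.Series  # post weeks, ug m-3
    pre_fitted: pd.Series  # augmented fit over pre weeks
    pre_rmse: float
    lower: pd.Series | None = None  # Jackknife+ band on the counterfactual
    upper: pd.Series | None = None

    @property
    def effect(self) -> pd.Series:
        """Weekly causal effect: observed minus counterfactual."""
        return self.panel.treated.loc[self.counterfactual.index] - self.counterfactual

    @property
    def effect_lower(self) -> pd.Series | None:
        if self.upper is None:
            return None
        return self.panel.treated.loc[self.upper.index] - self.upper

    @property
    def effect_upper(self) -> pd.Series | None:
        if self.lower is None:
            return None
        return self.panel.treated.loc[self.lower.index] - self.lower

    def to_dict(self) -> dict:
        return {
            "donors": self.panel.donor_names,
            "scm_weights": self.scm_weights.tolist(),
            "aug_weights": self.aug_weights.tolist(),
            "lambda": self.lam,
            "pre_rmse": self.pre_rmse,
        }


def predict_counterfactual(
    panel: WeeklyPanel,
    scm_weights: np.ndarray,
    lam: float,
) -> AscmFit:
    """Assemble the augmented fit: counterfactuals and augmented weights.

    The augmented weights are materialized from the ridge normal
    equations so that w^aug . Y_T reproduces the SCM-plus-ridge-correction
    form identically for every week.
    """
    x1, xd = panel.x1, panel.xd
    if xd.shape[1] != len(scm_weights):
        raise ValueError("weight vector does not match donor count")
    X = xd.T  # (J, p)
    p = X.shape[1]
    v = x1 - xd @ scm_weights  # pre-period residual vector
    correction = _ridge_solve(X.T @ X + lam * np.eye(p), v)  # (p,)
    aug = scm_weights + X @ correction

    all_weeks = panel.treated.index
    Y = panel.donors.loc[all_weeks].to_numpy(dtype=float)  # (n, J)
    fitted = pd.Series(Y @ aug, index=all_weeks)
    post = panel.post_weeks
    pre = panel.pre_weeks
    pre_resid = panel.treated.loc[pre] - fitted.loc[pre]
    return AscmFit(
        panel=panel,
        scm_weights=np.asarray(scm_weights, dtype=float),
        lam=float(lam),
        aug_weights=aug,
        counterfactual=fitted.loc[post],
        pre_fitted=fitted.loc[pre],
        pre_rmse=float(np.sqrt(np.mean(pre_resid**2))),
    )


def fit_ascm(
    panel: WeeklyPanel,
    lam: float | None = None,
    alpha: float | None = 0.05,
) -> AscmFit:
    """Full pipeline: SCM weights, ridge penalty, counterfactual, bands."""
    w = fit_scm_weights(panel)
    if lam is None:
        lam = select_lambda(panel)
    fit = predict_counterfactual(panel, w, lam)
    if alpha is not None and panel.donors.shape[1] >= 3:
        lower, upper = jackknife_plus(panel, fit, alpha=alpha)
        fit.lower, fit.upper = lower, upper
    return fit


# ---------------------------------------------------------------------------
# Jackknife+ intervals
# ---------------------------------------------------------------------------

def jackknife_plus(
    panel: WeeklyPanel,
    fit: AscmFit,
    alpha: float = 0.05,
) -> tuple[pd.Series, pd.Series]:
    """Jackknife+ band for the counterfactual, leaving out donor units.

    For each donor j the model is refit without j, giving a leave-one-out
    counterfactual; j's own predictability is scored by treating it as a
    pseudo-treated unit synthesized from the remaining donors, with
    residual e_j = mean |pre-period fit error|.  The band at week T uses
    the Jackknife+ order statistics: the floor(alpha (J+1))-th smallest
    of {Yhat^(-j) - e_j} and the ceil((1-alpha)(J+1))-th smallest of
    {Yhat^(-j) + e_j} (clamped to min/max when out of range).
    """
    names = panel.donor_names
    J = len(names)
    if J < 3:
        raise InsufficientDonorsError("Jackknife+ needs at least 3 donors")
    post = panel.post_weeks
    loo_cf = np.empty((J, len(post)))
    resid = np.empty(J)
    for i, name in enumerate(names):
        sub = panel.drop_donor(name)
        w = fit_scm_weights(sub)
        sub_fit = predict_counterfactual(sub, w, fit.lam)
        loo_cf[i] = sub_fit.counterfactual.to_numpy()

        pseudo = panel.pseudo_treated(name)
        pw = fit_scm_weights(pseudo)
        pfit = predict_counterfactual(pseudo, pw, fit.lam)
        err = pseudo.treated.loc[pseudo.pre_weeks] - pfit.pre_fitted
        resid[i] = float(np.mean(np.abs(err)))

    lo_vals = np.sort(loo_cf - resid[:, None], axis=0)
    hi_vals = np.sort(loo_cf + resid[:, None], axis=0)
    lo_k = int(np.floor(alpha * (J + 1)))  # index into sorted (1-based)
    hi_k = int(np.ceil((1.0 - alpha) * (J + 1)))
    lo_idx = max(lo_k - 1, 0)
    hi_idx = min(hi_k - 1, J - 1)
    lower = pd.Series(lo_vals[lo_idx], index=post)
    upper = pd.Series(hi_vals[hi_idx], index=post)
    return lower, upper


def jackknife_plus_weeks(
    panel: WeeklyPanel,
    fit: AscmFit,
    alpha: float = 0.05,
) -> tuple[pd.Series, pd.Series]:
    """Leave-one-week-out variant of the band (alternative reading).

    Drops each pre-period week in turn, refits, and combines the
    resulting counterfactuals with the dropped week's absolute augmented
    residual through the same order statistics.  Offered for comparison;
    the donor-unit jackknife above is the default.
    """
    pre = panel.pre_weeks
    n = len(pre)
    if n < 3:
        raise ValueError("need at least 3 pre-period weeks")
    post = panel.post_weeks
    loo_cf = np.empty((n, len(post)))
    resid = np.empty(n)
    for i, wk in enumerate(pre):
        keep = panel.treated.index.difference([wk])
        sub = WeeklyPanel(
            treated=panel.treated.loc[keep],
            donors=panel.donors.loc[keep],
            intervention=panel.intervention,
        )
        w = fit_scm_weights(sub)
        sub_fit = predict_counterfactual(sub, w, fit.lam)
        loo_cf[i] = sub_fit.counterfactual.to_numpy()
        resid[i] = abs(
            float(panel.treated.loc[wk])
            - float(panel.donors.loc[wk].to_numpy() @ sub_fit.aug_weights)
        )
    lo_vals = np.sort(loo_cf - resid[:, None], axis=0)
    hi_vals = np.sort(loo_cf + resid[:, None], axis=0)
    lo_idx = max(int(np.floor(alpha * (n + 1))) - 1, 0)
    hi_idx = min(int(np.ceil((1.0 - alpha) * (n + 1))) - 1, n - 1)
    return pd.Series(lo_vals[lo_idx], index=post), pd.Series(hi_vals[hi_idx], index=post)


# ---------------------------------------------------------------------------
# Donor screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    retained: list[str] = field(default_factory=list)
    removed: dict = field(default_factory=dict)  # name -> reason


def screen_donors(
    candidates: dict[str, pd.Series],
    treated: pd.Series,
    z_threshold: float = 5.0,
) -> ScreeningReport:
    """Remove donor series with abnormal pre-period behaviour.

    A candidate is dropped if (a) any pre-period week is missing, (b) any
    pre-period week is a robust outlier (|z| > 5 on the median/MAD
    scale), or (c) its pre-period Pearson correlation with the treated
    series is negative.
    """
    if len(candidates) < 3:
        raise InsufficientDonorsError("need at least 3 candidate donors")
    pre_idx = treated.index[treated.index < 0]
    t_pre = treated.loc[pre_idx]
    report = ScreeningReport()
    for name, series in candidates.items():
        pre = series.reindex(pre_idx)
        if pre.isna().any():
            report.removed[name] = "missing pre-period weeks"
            continue
        med = float(pre.median())
        mad = float((pre - med).abs().median())
        scale = 1.4826 * mad
        if scale > 0:
            z = (pre - med).abs() / scale
            if (z > z_threshold).any():
                report.removed[name] = (
                    f"outlier pre-period week (max |z| = {float(z.max()):.1f})"
                )
                continue
        if float(np.std(pre)) > 0 and float(np.std(t_pre)) > 0:
            corr = float(np.corrcoef(pre, t_pre)[0, 1])
            if corr < 0:
                report.removed[name] = f"negative pre-period correlation ({corr:.2f})"
                continue
        report.retained.append(name)
    if len(report.retained) < 2:
        raise InsufficientDonorsError(
            f"only {len(report.retained)} donors survive screening"
        )
    return report
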