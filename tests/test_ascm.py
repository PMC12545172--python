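"""Synthetic-control estimation: weights, augmentation, intervals, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aqcausal.ascm import (
    InsufficientDonorsError,
    WeeklyPanel,
    fit_ascm,
    fit_ridge_coefficients,
    fit_scm_weights,
    jackknife_plus,
    predict_counterfactual,
    scm_objective,
    screen_donors,
    to_weekly,
)
from aqcausal.synth import simulate_weekly_panel


def _random_panel(seed, n_donors=3, n_pre=10, n_post=4, scale=10.0):
    rng = np.random.default_rng(seed)
    weeks = np.arange(-n_pre, n_post)
    donors = pd.DataFrame(
        rng.normal(40, scale, (len(weeks), n_donors)),
        index=weeks,
        columns=[f"D{j}" for j in range(n_donors)],
    )
    treated = pd.Series(rng.normal(40, scale, len(weeks)), index=weeks)
    return WeeklyPanel(treated=treated, donors=donors)


# ---------------------------------------------------------------------------
# Weekly averaging
# ---------------------------------------------------------------------------

class TestToWeekly:
    intervention = pd.Timestamp("2019-04-08")

    def _hourly(self, values, start="2019-03-01"):
        idx = pd.date_range(start, periods=len(values), freq="h")
        return pd.Series(values, index=idx)

    def test_constant_series(self):
        s = self._hourly(np.full(24 * 28, 7.5))
        weekly = to_weekly(s, self.intervention)
        assert (weekly.dropna() == 7.5).all()

    def test_alternating_values_average(self):
        s = self._hourly(np.tile([10.0, 20.0], 84), start="2019-04-08")
        weekly = to_weekly(s, self.intervention)
        assert weekly.loc[0] == 15.0

    def test_incomplete_week_is_missing(self):
        vals = np.full(24 * 14, 5.0)
        vals[: 48] = np.nan  # week 0 keeps 120/168 hours = 71.4%
        s = self._hourly(vals, start="2019-04-08")
        weekly = to_weekly(s, self.intervention)
        assert np.isnan(weekly.loc[0])
        assert weekly.loc[1] == 5.0

    def test_week_zero_anchored_at_intervention(self):
        s = self._hourly(np.arange(24 * 21, dtype=float), start="2019-04-01")
        weekly = to_weekly(s, self.intervention)
        first_post_hours = s[
            (s.index >= self.intervention)
            & (s.index < self.intervention + pd.Timedelta(days=7))
        ]
        assert weekly.loc[0] == first_post_hours.mean()
        assert weekly.index.min() == -1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="week"):
            to_weekly(self._hourly(np.ones(100)), self.intervention)


# ---------------------------------------------------------------------------
# SCM weights
# ---------------------------------------------------------------------------

class TestScmWeights:
    def test_exact_convex_representation(self):
        rng = np.random.default_rng(0)
        weeks = np.arange(-10, 3)
        a = pd.Series(rng.normal(50, 8, len(weeks)), index=weeks)
        b = pd.Series(rng.normal(30, 8, len(weeks)), index=weeks)
        panel = WeeklyPanel(treated=0.3 * a + 0.7 * b, donors=pd.DataFrame({"a": a, "b": b}))
        w = fit_scm_weights(panel)
        np.testing.assert_allclose(w, [0.3, 0.7], atol=1e-6)

    def test_identical_donor_dominates_noise_donors(self):
        rng = np.random.default_rng(1)
        weeks = np.arange(-20, 4)
        treated = pd.Series(40 + 5 * np.sin(weeks / 3.0), index=weeks)
        donors = pd.DataFrame(
            {
                "twin": treated.to_numpy(),
                "n1": rng.normal(40, 10, len(weeks)),
                "n2": rng.normal(40, 10, len(weeks)),
            },
            index=weeks,
        )
        w = fit_scm_weights(WeeklyPanel(treated=treated, donors=donors))
        assert w[0] > 0.999

    def test_objective_matches_simplex_grid_search(self):
        """Exhaustive 0.001-step simplex enumeration as the oracle."""
        panel = _random_panel(seed=7, n_donors=3, n_pre=10)
        w = fit_scm_weights(panel)
        obj = scm_objective(panel, w)
        step = 0.001
        grid = np.arange(0.0, 1.0 + step / 2, step)
        w1, w2 = np.meshgrid(grid, grid, indexing="ij")
        keep = w1 + w2 <= 1.0 + 1e-12
        W = np.stack([w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]], axis=1)
        resid = W @ panel.xd.T - panel.x1
        grid_best = float(np.min(np.sum(resid**2, axis=1)))
        assert obj <= grid_best + 1e-9  # the QP can only do better
        assert grid_best - obj <= 1e-4 * max(1.0, grid_best)

    def test_weights_on_simplex(self):
        for seed in range(5):
            panel = _random_panel(seed, n_donors=6)
            w = fit_scm_weights(panel)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Ridge augmentation
# ---------------------------------------------------------------------------

class TestRidge:
    def test_negative_penalty_rejected(self):
        panel = _random_panel(0)
        with pytest.raises(ValueError):
            fit_ridge_coefficients(panel, -1.0, post_week=0)

    def test_matches_normal_equations_oracle(self):
        panel = _random_panel(seed=3, n_donors=8, n_pre=6)
        eta = fit_ridge_coefficients(panel, lam=1.0, post_week=0)
        X = panel.xd.T
        y = panel.donors.loc[0].to_numpy()
        oracle = np.linalg.inv(X.T @ X + np.eye(6)) @ X.T @ y
        np.testing.assert_allclose(eta, oracle, rtol=1e-10)

    def test_zero_penalty_interpolates_exact_linear_relation(self):
        rng = np.random.default_rng(5)
        n_pre, n_donors = 4, 9  # more donors than pre-period weeks
        eta_true = rng.normal(size=n_pre)
        X = rng.normal(40, 10, (n_donors, n_pre))
        y_post = X @ eta_true
        weeks = np.arange(-n_pre, 1)
        donors = pd.DataFrame(
            np.vstack([X.T, y_post]), index=weeks,
            columns=[f"D{j}" for j in range(n_donors)],
        )
        treated = pd.Series(rng.normal(40, 10, len(weeks)), index=weeks)
        panel = WeeklyPanel(treated=treated, donors=donors)
        eta = fit_ridge_coefficients(panel, lam=0.0, post_week=0)
        np.testing.assert_allclose(eta, eta_true, atol=1e-8)

    def test_infinite_penalty_limit_collapses_to_scm(self):
        panel = _random_panel(seed=2, n_donors=5)
        w = fit_scm_weights(panel)
        scm_cf = panel.donors.loc[panel.post_weeks].to_numpy() @ w
        fit = predict_counterfactual(panel, w, lam=1e12)
        np.testing.assert_allclose(fit.counterfactual.to_numpy(), scm_cf, rtol=1e-6)
        eta = fit_ridge_coefficients(panel, lam=1e12, post_week=0)
        assert np.abs(eta).max() < 1e-6

    def test_collapse_to_scm_is_monotone_along_lambda_grid(self):
        panel = _random_panel(seed=9, n_donors=5, n_pre=12)
        w = fit_scm_weights(panel)
        scm_cf = panel.donors.loc[panel.post_weeks].to_numpy() @ w
        dists = []
        for lam in np.logspace(-2, 8, 11):
            fit = predict_counterfactual(panel, w, lam=lam)
            dists.append(np.linalg.norm(fit.counterfactual.to_numpy() - scm_cf))
        diffs = np.diff(dists)
        assert np.all(diffs <= 1e-9)


# ---------------------------------------------------------------------------
# Counterfactual prediction
# ---------------------------------------------------------------------------

class TestCounterfactual:
    def test_zero_residual_pre_fit_disables_augmentation(self):
        rng = np.random.default_rng(0)
        weeks = np.arange(-10, 3)
        a = pd.Series(rng.normal(50, 8, len(weeks)), index=weeks)
        b = pd.Series(rng.normal(30, 8, len(weeks)), index=weeks)
        panel = WeeklyPanel(treated=0.4 * a + 0.6 * b, donors=pd.DataFrame({"a": a, "b": b}))
        w = fit_scm_weights(panel)
        fit = predict_counterfactual(panel, w, lam=1.0)
        scm_cf = panel.donors.loc[panel.post_weeks].to_numpy() @ w
        np.testing.assert_allclose(fit.counterfactual.to_numpy(), scm_cf, atol=1e-4)

    def test_treated_identical_to_donor(self):
        rng = np.random.default_rng(4)
        weeks = np.arange(-12, 5)
        twin = pd.Series(40 + 6 * np.cos(weeks / 4.0), index=weeks)
        donors = pd.DataFrame(
            {"twin": twin, "other": rng.normal(40, 10, len(weeks))}, index=weeks
        )
        fit = fit_ascm(WeeklyPanel(treated=twin.copy(), donors=donors), alpha=None)
        np.testing.assert_allclose(
            fit.counterfactual.to_numpy(),
            twin.loc[fit.counterfactual.index].to_numpy(),
            rtol=1e-6,
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_augmented_weight_identity(self, seed):
        """w_aug . Y_T equals the SCM-plus-ridge-correction form exactly."""
        panel = _random_panel(seed, n_donors=5, n_pre=8, n_post=5)
        w = fit_scm_weights(panel)
        lam = 0.7
        fit = predict_counterfactual(panel, w, lam)
        for week in panel.post_weeks:
            eta = fit_ridge_coefficients(panel, lam, post_week=week)
            y = panel.donors.loc[week].to_numpy()
            direct = w @ y + (panel.x1 - panel.xd @ w) @ eta
            via_aug = fit.aug_weights @ y
            assert via_aug == pytest.approx(direct, rel=1e-8)

    def test_dimension_mismatch_rejected(self):
        panel = _random_panel(0, n_donors=4)
        with pytest.raises(ValueError):
            predict_counterfactual(panel, np.array([0.5, 0.5]), lam=1.0)

    def test_null_effect_gap_within_pre_rmse_noise(self):
        gaps, rmses = [], []
        for seed in range(20):
            treated, donors, _ = simulate_weekly_panel(
                n_donors=10, n_pre=30, n_post=8, effect_size=0.0, seed=seed
            )
            fit = fit_ascm(WeeklyPanel(treated=treated, donors=donors), alpha=None)
            gaps.append(float(fit.effect.mean()))
            rmses.append(fit.pre_rmse)
        assert abs(np.mean(gaps)) <= 2.0 * np.mean(rmses)


# ---------------------------------------------------------------------------
# Jackknife+
# ---------------------------------------------------------------------------

class TestJackknifePlus:
    def test_identical_donors_give_degenerate_interval(self):
        weeks = np.arange(-8, 3)
        base = pd.Series(40 + np.sin(weeks / 2.0), index=weeks)
        donors = pd.DataFrame({f"D{j}": base for j in range(4)}, index=weeks)
        panel = WeeklyPanel(treated=base.copy(), donors=donors)
        fit = fit_ascm(panel, lam=0.0, alpha=0.05)
        np.testing.assert_allclose(fit.lower, fit.counterfactual, atol=1e-6)
        np.testing.assert_allclose(fit.upper, fit.counterfactual, atol=1e-6)

    def test_wider_alpha_gives_nested_intervals(self):
        panel = _random_panel(seed=8, n_donors=8, n_pre=15)
        fit = fit_ascm(panel, alpha=None)
        lo05, hi05 = jackknife_plus(panel, fit, alpha=0.05)
        lo50, hi50 = jackknife_plus(panel, fit, alpha=0.5)
        assert (lo50 >= lo05 - 1e-12).all()
        assert (hi50 <= hi05 + 1e-12).all()

    def test_too_few_donors_rejected(self):
        panel = _random_panel(0, n_donors=2)
        fit = fit_ascm(panel, alpha=None)
        with pytest.raises(InsufficientDonorsError):
            jackknife_plus(panel, fit)

    def test_permutation_sanity_on_null_panels(self):
        """Pseudo-treating donors brackets the true-treated null estimate."""
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            treated, donors, _ = simulate_weekly_panel(
                n_donors=10, n_pre=25, n_post=6, effect_size=0.0, seed=300 + seed
            )
            panel = WeeklyPanel(treated=treated, donors=donors)
            fit = fit_ascm(panel, alpha=None)
            true_est = abs(float(fit.effect.mean()))
            placebo = []
            for name in panel.donor_names:
                pfit = fit_ascm(panel.pseudo_treated(name), alpha=None)
                placebo.append(abs(float(pfit.effect.mean())))
            if np.quantile(placebo, 0.95) >= true_est:
                wins += 1
        assert wins >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# Donor screening
# ---------------------------------------------------------------------------

class TestScreening:
    def _weekly(self, values):
        weeks = np.arange(-len(values) + 4, 4)
        return pd.Series(values, index=weeks)

    def test_clean_donors_all_retained(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=6, n_pre=20, seed=0)
        report = screen_donors({c: donors[c] for c in donors}, treated)
        assert sorted(report.retained) == sorted(donors.columns)
        assert report.removed == {}

    def test_spike_removed_by_mad_rule(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=5, n_pre=20, seed=1)
        spiked = donors.copy()
        pre_weeks = spiked.index[spiked.index < 0]
        spiked.loc[pre_weeks[3], "D01"] = 50 * spiked["D01"].median()
        report = screen_donors({c: spiked[c] for c in spiked}, treated)
        assert "D01" in report.removed
        assert "outlier" in report.removed["D01"]

    def test_missing_pre_week_removed(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=5, n_pre=20, seed=2)
        holed = donors.copy()
        holed.loc[holed.index[2], "D02"] = np.nan
        report = screen_donors({c: holed[c] for c in holed}, treated)
        assert report.removed["D02"] == "missing pre-period weeks"

    def test_donor_equal_to_treated_retained(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=4, n_pre=20, seed=3)
        cands = {c: donors[c] for c in donors}
        cands["copycat"] = treated.copy()
        report = screen_donors(cands, treated)
        assert "copycat" in report.retained

    def test_anticorrelated_donor_removed(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=4, n_pre=20, seed=4)
        pre = treated.index[treated.index < 0]
        flipped = treated.copy()
        flipped.loc[pre] = 2 * float(treated.loc[pre].mean()) - treated.loc[pre]
        cands = {c: donors[c] for c in donors}
        cands["mirror"] = flipped
        report = screen_donors(cands, treated)
        assert "mirror" in report.removed
        assert "correlation" in report.removed["mirror"]

    def test_too_few_candidates_rejected(self):
        treated, donors, _ = simulate_weekly_panel(n_donors=2, n_pre=10, seed=5)
        with pytest.raises(InsufficientDonorsError):
            screen_donors({c: donors[c] for c in donors}, treated)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fit_invariants_on_random_panels(seed):
    """Simplex validity and the augmented-weight identity on arbitrary data."""
    panel = _random_panel(seed, n_donors=4, n_pre=9, n_post=3)
    fit = fit_ascm(panel, alpha=None)
    assert np.all(fit.scm_weights >= 0)
    assert fit.scm_weights.sum() == pytest.approx(1.0, abs=1e-10)
    week = panel.post_weeks[0]
    eta = fit_ridge_coefficients(panel, fit.lam, post_week=week)
    y = panel.donors.loc[week].to_numpy()
    direct = fit.scm_weights @ y + (panel.x1 - panel.xd @ fit.scm_weights) @ eta
    assert fit.aug_weights @ y == pytest.approx(direct, rel=1e-8, abs=1e-8)
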