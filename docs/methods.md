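# Methods

`aqcausal` estimates the causal effect of an air-quality intervention (a
low-emission-zone-style policy) on pollutant concentrations by combining
two stages: machine-learning *weather normalization* of hourly monitoring
data, and a *ridge-augmented synthetic control* fitted to weekly averages
of the normalized series, with Jackknife+ prediction intervals.  Because
the package is exercised on synthetic panels with known ground truth,
every stage can be scored against the answer it should recover.

## 1. Data model and quality control

The unit of data is one monitoring site's hourly record: pollutant
concentrations (NO2, NOx, PM2.5, µg m⁻³) and nine meteorological
variables (temperature, relative humidity, wind speed and direction,
surface net solar radiation, precipitation, boundary-layer height, total
cloud cover, surface pressure).  Timestamps form a strict hourly UTC
grid; gaps are missing values, never absent rows.

Two completeness filters are applied before modelling, both with strict
inequalities:

* a calendar day (UTC) is **valid** for a pollutant only if more than
  75% of its 24 hours are present — 18/24 hours (exactly 75%) fails,
  19/24 passes;
* a site is **included** only if more than 80% of study-window days are
  valid — 584/730 days (exactly 80%) fails, 585/730 passes.

Validity is assessed per pollutant: a site can be included for NOx and
excluded for PM2.5.  Group (zone × site-type) series are hourly
arithmetic means over included sites, ignoring missing values; an hour
missing everywhere is missing in the aggregate.  For the causal
analysis, aggregation is applied to *per-site weather-normalized*
series (normalize first, then average), because the normalization model
is defined per site; aggregation of raw series is available for
diagnostics.

## 2. Weather normalization

For each site and pollutant a random forest (300 trees, minimum
terminal node size 5 — the configuration standard in the deweathering
literature) predicts the hourly concentration from the nine
meteorological variables plus four deterministic time proxies: Unix
time (long-term trend), day of year (seasonal cycle), day of week
(weekly cycle) and hour of day (diel cycle).  Wind direction enters as
sine/cosine components to remove the 0°/360° discontinuity.  The model
is fit on a random 70% of complete rows; held-out bias (mean of
predicted − observed) and Pearson correlation are computed on the
remaining 30%, and a model is flagged when |bias| exceeds 10% of the
target mean or r ≤ 0.7.

The weather-normalized value for hour *t* is the arithmetic mean of the
forest's predictions over resampled meteorology: the time proxies stay
at their actual values while the meteorological vector is replaced by
that of a randomly drawn comparable hour.  Comparable hours share *t*'s
hour of day and lie within ±14 calendar days of *t*'s month-day,
anchored in **every** year of the record (including *t*'s own year),
with windows wrapping across year boundaries; for a two-year record a
pool therefore holds up to 58 members.  By default 150 draws are made
without replacement; when the pool is smaller than the requested count,
every pool member is used exactly once, making the normalized value
deterministic.  Meteorology is resampled **jointly** — a whole observed
hour's vector at a time — so the physical covariance among variables
(e.g. wind speed vs boundary-layer height) is preserved; per-variable
resampling would generate meteorologically impossible combinations.

Because forest predictions are averages of training targets, the
normalized series cannot leave the range of observed concentrations,
and increasing the number of draws shrinks the Monte-Carlo error with
the without-replacement variance law Var ∝ (1/n − 1/N).

## 3. Ridge-augmented synthetic control

Hourly normalized series are averaged into 7-day blocks anchored at the
intervention instant (week 0 starts exactly at the policy date); a week
with fewer than 75% of its expected hourly slots is missing.  Let
X₁ ∈ ℝᵖ be the treated unit's pre-period weekly vector, Xⱼ the donors',
and Y_jT the donors' outcome at post week T.  The counterfactual is

    Ŷ₁T = Σⱼ ŵⱼˢᶜᵐ Y_jT + (X₁ − Σⱼ ŵⱼˢᶜᵐ Xⱼ)·η̂ᴿⁱᵈᵍᵉ = Σⱼ ŵⱼᵃᵘᵍ Y_jT ,

with ŵˢᶜᵐ = argmin‖X₁ − Xw‖² over the probability simplex and η̂ᴿⁱᵈᵍᵉ
the ridge regression of donors' week-T outcomes on their pre-period
vectors.  Substituting the ridge normal equations gives post-week-
independent augmented weights
ŵᵃᵘᵍ = ŵˢᶜᵐ + X(XᵀX + λI)⁻¹(X₁ − Xᵀŵˢᶜᵐ); the package materializes
these and verifies the identity between the two forms to 1e-8 relative
tolerance on every fit.  The weekly causal effect is observed minus
counterfactual.

Numerical choices:

* **Simplex QP.** The sum-to-one constraint is folded into the
  least-squares system as a heavily weighted penalty row and solved with
  the exact active-set NNLS algorithm, then renormalized; a vanishing
  ridge term (1e-10 relative) breaks ties toward the minimum-norm
  weights.  This is robust where sequential quadratic programming stalls
  on flat objectives, and matches exhaustive simplex grid search to
  better than 1e-4 in the objective.
* **Ridge solve.** Regularized normal equations via `numpy.linalg.solve`,
  falling back to the pseudo-inverse (minimum-norm solution) when λ = 0
  and the pre-period Gram matrix is singular.
* **λ selection.** When not supplied, λ is chosen by leave-one-donor-out
  cross-validation over a 13-point log grid spanning 1e-3–1e3 times the
  pre-period outcome variance, scoring the squared error of predicting
  each held-out donor's post-week outcomes.  λ → ∞ provably collapses
  the estimator onto plain SCM; the package tests that this collapse is
  monotone.

**Donor screening.** Before fitting, candidate donors are dropped if
any pre-period week is missing, if a pre-period week is a robust
outlier (|z| > 5 on the median/MAD scale), or if their pre-period
correlation with the treated series is negative.

**Jackknife+ intervals.** Each donor j is left out in turn and the full
estimator refit, giving Ŷ₁T⁽⁻ʲ⁾; donor j's own predictability is scored
by synthesizing it from the remaining donors and averaging its absolute
pre-period fit residual, eⱼ.  The band at week T is formed from the
Jackknife+ order statistics: the ⌊α(J+1)⌋-th smallest of
{Ŷ₁T⁽⁻ʲ⁾ − eⱼ} and the ⌈(1−α)(J+1)⌉-th smallest of {Ŷ₁T⁽⁻ʲ⁾ + eⱼ}
(clamped to the extremes when the index leaves the range, as happens at
α = 0.05 with J ≤ 19).  The jackknife is taken over **donor units**,
the established construction for synthetic controls; a
leave-one-week-out variant is provided behind a separate function for
comparison, without any claim of equivalence.  Leave-one-out refits
reuse the full fit's λ rather than re-running cross-validation — the
penalty describes the outcome model's smoothness, not the donor set,
and re-selection inside the jackknife would mix model-selection noise
into the interval.

## 4. Effect summaries

The relative effect over a window is P = (C_wn − C_cf)/C_cf × 100,
where C_wn and C_cf are the means of the weekly observed (normalized)
and counterfactual values over the included weeks.  Windows are
calendar months (1/3/6/9/11) measured from the intervention date;
post-intervention weeks 0 and 1 — the transition period — are always
excluded, so the first included week starts 14 days after the policy.
A window whose weeks are not fully covered by data is an error, not a
truncation.  The 95% band on a windowed effect averages the weekly
Jackknife+ bounds — a conservative propagation; exact joint inference
over weeks is out of scope.  A window's effect is called significant
when that band excludes zero.

**Traffic increments.** The urban-traffic minus urban-background group
mean, compared between a pre-intervention window (matching the causal
model's pre-fit span) and the post-policy window.  On simulated data
with a traffic-site-only effect, the increment change and the
synthetic-control absolute effect should agree — a cross-check of the
estimator against a design-based quantity.

**Placebo-in-time.** The full estimator re-anchored at a
pseudo-intervention date (e.g. the policy announcement), using only
data from before the true intervention; a significant 3-month effect
there indicates a spurious signal.

**Peak-hour sensitivity.** The pipeline rerun on hours 06–09 only
(weekly completeness threshold scaled to the 28 available slots); with
an hour-independent effect the relative estimate should move by less
than one percentage point.

## 5. Synthetic data generator

The generator emulates the structure the method assumes rather than any
particular city's data.  Hourly concentrations are built as

    C(t) = E(t) · policy(t) · M(t) · exp(ε_t)

* **E(t)** — emission component: baseline × seasonal cycle (cosine
  peaking mid-January, amplitude 0.25) × diurnal profile (24 factors
  with morning/evening traffic peaks, mean 1) × weekday factors
  (weekdays ≈ 1.05, weekend ≈ 0.83–0.92, mean 1) × slow trend
  (−3%/year).  Default baselines are typical UK urban annual means:
  urban background 28/45/11 µg m⁻³ and urban traffic 55/130/14 µg m⁻³
  for NO2/NOx/PM2.5.
* **policy(t)** — 1 before the intervention; 1 − δ afterwards at
  treated sites (δ = 0.15 by default, configurable per site type and,
  for sensitivity scenarios, per hour of day).  Donors always have
  multiplier 1, so regenerating with a different δ cannot change them.
* **M(t)** — meteorological modulation exp(−k_ws·ws)·(blh_ref/blh)^k_blh
  (dilution by wind speed, k_ws = 0.12 per m s⁻¹, and by boundary-layer
  height, exponent 0.30, referenced to the period-mean BLH), normalized
  to mean 1 over the period so E(t) is exactly the weather-averaged
  concentration the deweathering stage should recover.
* **ε_t** — Gaussian on the log scale with σ = 0.3: concentrations are
  positive and right-skewed, and multiplicative noise keeps them so.

Meteorology has deterministic seasonal/diurnal structure plus AR(1)
noise with lag-1 autocorrelation 0.8 (hour-to-hour weather
persistence), with physical bounds enforced (ws ≥ 0, blh > 0,
cloud cover ∈ [0,1], wind direction ∈ [0,360)).  All treated-region
sites share one meteorology draw; every donor city gets its own — this
is what makes weather normalization necessary before cross-city
comparison.  Missingness is random hourly deletion at 2% by default.
Per-site random streams are derived by stable hashing of (master seed,
site id), so adding sites never perturbs existing series.  The default
study window is the two years 2018-03-08 to 2020-03-08 with the
intervention on 2019-04-08.

A companion weekly-scale generator (`simulate_weekly_panel`) produces
what the hourly pipeline delivers to the synthetic-control stage
directly: weekly outcomes with a shared seasonal cycle and trend,
unit-specific levels and loadings, a treated unit near the donor convex
hull, and residual noise σ = 0.025 — the weekly remnant of hourly
lognormal noise with σ = 0.3 averaged over 168 hours.  Monte-Carlo
studies of the estimator (recovery, coverage, false-positive rate,
placebo) run at this scale; running 50 seeds of the full hourly
deweathering pipeline per study is not a sensible use of compute when
the weekly statistics are what the estimator consumes.

What the generator does **not** emulate: atmospheric chemistry
(NO/NO2/O3 conversion), spatial dispersion, long-range transport,
instrument drift or ratification artifacts, and correlated multi-day
missingness episodes (block gaps are available but off by default).
Passing tests therefore demonstrate that the estimator recovers effects
under the model's own assumptions — exchangeable donors, multiplicative
weather, stable seasonal structure — not that those assumptions hold
for any particular monitoring network.

## 6. Problem sizes and diagnostic scenarios

The shipped studies use sizes chosen to make each question answerable
on a single CPU in minutes: forest quality and emission-component
recovery on one two-year site record (seed 1, 150 resamples); the
null-step check on twenty one-year records with a 100-tree forest and a
±8-week evaluation window around the placebo date; estimator recovery
and calibration on 50 weekly panels with 15 donors, 40 pre- and 12–14
post-intervention weeks.

Two diagnostics deliberately switch the meteorological coupling off
(k_ws = k_blh = 0), making the observed series coincide with its
weather-normalized version, so the effects logic is validated
independently of the forest stage: the traffic-increment cross-check
(which additionally uses a season-free emission profile, because an
increment compared across seasonally different windows is confounded by
the shared seasonal cycle — a design property, not an estimator error)
and the peak-hour sensitivity comparison.

## 7. Known limitations

* The window-averaged significance call uses conservatively averaged
  weekly bounds; it under-rejects relative to an exact joint test.
* Jackknife+ guarantees are for exchangeable regression residuals; the
  donor-unit jackknife over a fitted synthetic control inherits them
  only approximately.  Empirical coverage is verified by simulation.
* With fewer than 19 donors the α = 0.05 order statistics clamp to the
  min/max, so the nominal level is conservative.
* Forests cannot extrapolate beyond observed concentrations, so a
  policy effect larger than anything in the training range would be
  attenuated in the normalized series.
* The percentage change is undefined for non-positive counterfactual
  means, and negative counterfactuals are reported as computed (with a
  warning), not clipped.
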