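"""Random-forest weather normalization ("deweathering") of hourly series.

For each site and pollutant a regression forest predicts the hourly
concentration from nine meteorological variables plus four time proxies
(Unix time for the long-term trend, day of year for the seasonal cycle,
day of week for the weekly cycle, hour of day for the diel cycle).  The
weather-normalized value for an hour is then the arithmetic mean of the
model's predictions when the meteorology is replaced by vectors resampled
from climatologically comparable hours — same hour of day, within a
+/-14-day calendar window around the target date in every year of the
record — while the time proxies are held at their actual values.  This
removes weather-driven variation but preserves the seasonal, weekly and
diel emission structure.

Meteorology vectors are resampled jointly (a whole observed hour at a
time) so the physical covariance among variables is preserved; wind
direction enters the forest as sine/cosine components to avoid the
0/360-degree discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .ingest import MET_COLUMNS, HourlySiteSeries

TIME_FEATURES = ("unix_time", "day_of_year", "day_of_week", "hour_of_day")
MET_FEATURES = (
    "temp_c",
    "rh_pct",
    "ws_ms",
    "wd_sin",
    "wd_cos",
    "ssr",
    "precip_mm",
    "blh_m",
    "tcc",
    "sp_hpa",
)
FEATURES = TIME_FEATURES + MET_FEATURES

MIN_TRAINING_ROWS = 100


class InsufficientDataError(ValueError):
    """Raised when a site/pollutant lacks enough complete rows to model."""


def time_proxies(index: pd.DatetimeIndex) -> pd.DataFrame:
    """The four deterministic time-proxy features for each timestamp.

    day_of_week is 1..7 with Monday = 1; day_of_year is 1..366.
    """
    return pd.DataFrame(
        {
            "unix_time": index.asi8 // 1_000_000_000,
            "day_of_year": index.dayofyear,
            "day_of_week": index.dayofweek + 1,
            "hour_of_day": index.hour,
        },
        index=index,
        dtype=float,
    )


def met_features(met: pd.DataFrame) -> pd.DataFrame:
    """Meteorology block with wind direction as (sin, cos) components."""
    wd = np.deg2rad(met["wd_deg"].to_numpy(dtype=float))
    out = pd.DataFrame(index=met.index)
    out["temp_c"] = met["temp_c"]
    out["rh_pct"] = met["rh_pct"]
    out["ws_ms"] = met["ws_ms"]
    out["wd_sin"] = np.sin(wd)
    out["wd_cos"] = np.cos(wd)
    out["ssr"] = met["ssr"]
    out["precip_mm"] = met["precip_mm"]
    out["blh_m"] = met["blh_m"]
    out["tcc"] = met["tcc"]
    out["sp_hpa"] = met["sp_hpa"]
    return out


def build_features(
    series: HourlySiteSeries, pollutant: str
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Feature matrix and target for one site/pollutant.

    Rows with a missing target or any missing meteorological predictor are
    dropped; the number dropped is returned alongside.
    """
    target = series.pollutant(pollutant)
    met = met_features(series.data[list(MET_COLUMNS)])
    X = pd.concat([time_proxies(series.index), met], axis=1)
    ok = target.notna() & X.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    X, y = X.loc[ok], target.loc[ok]
    if len(y) < MIN_TRAINING_ROWS:
        raise InsufficientDataError(
            f"only {len(y)} complete rows for {series.site_id}/{pollutant}; "
            f"need at least {MIN_TRAINING_ROWS}"
        )
    return X, y, n_dropped


@dataclass
class DeweatherModel:
    """A fitted weather-normalization forest plus held-out diagnostics."""

    forest: RandomForestRegressor
    feature_names: tuple
    train_index: np.ndarray
    test_index: np.ndarray
    bias: float  # mean(predicted - observed) on held-out rows, ug m-3
    pearson_r: float  # held-out correlation
    poor_fit: bool
    seed: int
    target_mean: float

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        return self.forest.predict(X)

    def diagnostics(self) -> dict:
        return {
            "bias": self.bias,
            "pearson_r": self.pearson_r,
            "poor_fit": self.poor_fit,
            "n_train": int(len(self.train_index)),
            "n_test": int(len(self.test_index)),
            "n_trees": int(self.forest.n_estimators),
            "min_node_size": int(self.forest.min_samples_leaf),
            "seed": self.seed,
        }


def train_model(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int,
    split: float = 0.7,
    n_trees: int = 300,
    min_node_size: int = 5,
) -> DeweatherModel:
    """Fit the forest on a random 70/30 split and record held-out quality.

    The forest uses 300 trees and a minimum terminal node size of 5 unless
    overridden.  A model is flagged ``poor_fit`` when its held-out bias
    exceeds 10% of the target mean in magnitude or its held-out Pearson
    correlation is <= 0.7.
    """
    if len(y) < MIN_TRAINING_ROWS:
        raise InsufficientDataError(f"need >= {MIN_TRAINING_ROWS} rows, got {len(y)}")
    if float(np.std(y)) == 0.0:
        raise ValueError("degenerate target: zero variance")
    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_node_size,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    Xv = X[list(FEATURES)].to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    forest.fit(Xv[train_idx], yv[train_idx])

    pred = forest.predict(Xv[test_idx])
    bias = float(np.mean(pred - yv[test_idx]))
    r = float(stats.pearsonr(pred, yv[test_idx]).statistic)
    mean = float(np.mean(yv))
    poor = (abs(bias) > 0.10 * abs(mean)) or (r <= 0.7)
    return DeweatherModel(
        forest=forest,
        feature_names=FEATURES,
        train_index=train_idx,
        test_index=test_idx,
        bias=bias,
        pearson_r=r,
        poor_fit=poor,
        seed=seed,
        target_mean=mean,
    )


# ---------------------------------------------------------------------------
# Restricted meteorology resampling
# ---------------------------------------------------------------------------

def candidate_pool(
    timestamp: pd.Timestamp,
    available: pd.DatetimeIndex,
    window_half_width: int = 14,
) -> pd.DatetimeIndex:
    """Timestamps eligible to lend their meteorology to `timestamp`.

    Candidates share the target's hour of day and fall within
    +/-``window_half_width`` calendar days of the target's month-day,
    anchored in every year spanned by ``available`` (including the
    target's own year); bounds inclusive, windows wrapping across year
    boundaries.
    """
    ts = pd.Timestamp(timestamp)
    if len(available) == 0:
        return pd.DatetimeIndex([])
    avail = pd.DatetimeIndex(available).sort_values()
    years = range(avail.min().year - 1, avail.max().year + 2)
    picked = set()
    day = pd.Timedelta(days=1)
    for year in years:
        try:
            anchor = ts.replace(year=year)
        except ValueError:  # 29 Feb in a non-leap year
            anchor = ts.replace(year=year, day=28)
        lo, hi = anchor - window_half_width * day, anchor + window_half_width * day
        span = avail[(avail >= lo) & (avail <= hi)]
        picked.update(span[span.hour == ts.hour])
    return pd.DatetimeIndex(sorted(picked))


def _pools_by_calendar_slot(
    targets: pd.DatetimeIndex,
    available: pd.DatetimeIndex,
    window_half_width: int,
) -> dict:
    """Candidate pools keyed by (month, day, hour).

    The anchored-window construction makes a pool depend only on the
    target's month-day and hour, so targets in different years share it.
    """
    pools = {}
    for slot in set(zip(targets.month, targets.day, targets.hour)):
        month, day, hour = slot
        rep = targets[
            (targets.month == month) & (targets.day == day) & (targets.hour == hour)
        ][0]
        pools[slot] = candidate_pool(rep, available, window_half_width)
    return pools


def normalize(
    model: DeweatherModel,
    series: HourlySiteSeries,
    pollutant: str,
    n_resamples: int = 150,
    window_half_width: int = 14,
    seed: int = 0,
    hours: pd.DatetimeIndex | None = None,
    chunk_rows: int = 300_000,
) -> pd.Series:
    """Weather-normalized hourly series for one site/pollutant.

    For each target hour, ``n_resamples`` distinct timestamps are drawn
    without replacement from the candidate pool (the whole pool, used
    exactly once, when it is smaller); the model predicts with the
    target's own time proxies and each drawn hour's meteorology, and the
    arithmetic mean of the predictions is returned.  Hours whose pool is
    empty are omitted.
    """
    if model is None or getattr(model, "forest", None) is None:
        raise RuntimeError("model must be trained before normalization")
    targets = series.index if hours is None else pd.DatetimeIndex(hours)
    met = met_features(series.data[list(MET_COLUMNS)])
    met_ok = met.index[met.notna().all(axis=1)]
    met_values = met.loc[met_ok].to_numpy(dtype=float)
    met_pos = pd.Series(np.arange(len(met_ok)), index=met_ok)

    pools = _pools_by_calendar_slot(targets, met_ok, window_half_width)
    rng = np.random.default_rng(seed)
    proxies = time_proxies(targets).to_numpy(dtype=float)

    kept_targets = []
    met_row_idx = []
    counts = []
    proxy_rows = []
    # Iterate targets in timestamp order so draws are order-independent
    # of how callers batch them.
    for i, ts in enumerate(targets):
        pool = pools[(ts.month, ts.day, ts.hour)]
        m = len(pool)
        if m == 0:
            continue
        pool_pos = met_pos.loc[pool].to_numpy()
        if m <= n_resamples:
            chosen = pool_pos
        else:
            chosen = rng.choice(pool_pos, size=n_resamples, replace=False)
        kept_targets.append(ts)
        counts.append(len(chosen))
        met_row_idx.append(chosen)
        proxy_rows.append(np.repeat(proxies[i : i + 1], len(chosen), axis=0))

    if not kept_targets:
        return pd.Series(dtype=float)
    X = np.hstack([np.vstack(proxy_rows), met_values[np.concatenate(met_row_idx)]])
    preds = np.empty(len(X))
    for lo in range(0, len(X), chunk_rows):
        preds[lo : lo + chunk_rows] = model.forest.predict(X[lo : lo + chunk_rows])
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    sums = np.add.reduceat(preds, offsets)
    values = sums / np.asarray(counts, dtype=float)
    return pd.Series(values, index=pd.DatetimeIndex(kept_targets), name=f"{pollutant}_wn")


def deweather_site(
    series: HourlySiteSeries,
    pollutant: str,
    seed: int,
    n_resamples: int = 150,
    window_half_width: int = 14,
    n_trees: int = 300,
    min_node_size: int = 5,
    hours: pd.DatetimeIndex | None = None,
) -> tuple[pd.Series, DeweatherModel]:
    """Convenience wrapper: build features, train, normalize one site."""
    X, y, _ = build_features(series, pollutant)
    model = train_model(X, y, seed=seed, n_trees=n_trees, min_node_size=min_node_size)
    wn = normalize(
        model,
        series,
        pollutant,
        n_resamples=n_resamples,
        window_half_width=window_half_width,
        seed=seed,
        hours=hours,
    )
    return wn, model
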