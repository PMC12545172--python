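"""Hourly site data: containers, CSV I/O, validity filters and aggregation.

Monitoring networks deliver hourly pollutant concentrations with gaps.
Before any modelling, two completeness filters are applied:

* a calendar day (UTC) is *valid* for a pollutant only if strictly more
  than 75% of its 24 hours are present (i.e. at least 19 hours);
* a site is *included* for a pollutant only if strictly more than 80% of
  the days in the study window are valid.

Included sites are then averaged into region x site-type group series,
ignoring missing values hour by hour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

POLLUTANTS = ("no2", "nox", "pm25")
MET_COLUMNS = (
    "temp_c",
    "rh_pct",
    "ws_ms",
    "wd_deg",
    "ssr",
    "precip_mm",
    "blh_m",
    "tcc",
    "sp_hpa",
)

DAY_VALIDITY_THRESHOLD = 0.75  # strict: a day needs > 75% of hours
SITE_INCLUSION_THRESHOLD = 0.80  # strict: a site needs > 80% valid days


@dataclass
class HourlySiteSeries:
    """One site's hourly pollutant + meteorology record.

    ``data`` is indexed by a strictly increasing hourly UTC grid; gaps are
    represented as NaN rows, never as absent rows.
    """

    site_id: str
    site_type: str
    zone: str
    data: pd.DataFrame

    def __post_init__(self):
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("data must be indexed by timestamps")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == 3_600_000_000_000):
                raise ValueError(
                    "timestamps must form a strictly increasing 1-hour grid "
                    "(represent gaps as NaN rows)"
                )
        for pol in POLLUTANTS:
            if pol in self.data.columns:
                vals = self.data[pol]
                if (vals.dropna() < 0).any():
                    raise ValueError(f"negative concentrations in {pol}")

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def pollutant(self, name: str) -> pd.Series:
        if name not in POLLUTANTS or name not in self.data.columns:
            raise KeyError(f"unknown pollutant {name!r}")
        return self.data[name]


def on_grid(data: pd.DataFrame) -> pd.DataFrame:
    """Reindex a timestamp-indexed frame onto its full hourly grid."""
    idx = data.index
    full = pd.date_range(idx.min(), idx.max(), freq="h")
    return data.reindex(full)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_site_csv(series: HourlySiteSeries, path: str | Path) -> None:
    """Write one site to CSV (empty cell = missing)."""
    df = series.data.copy()
    df.insert(0, "zone", series.zone)
    df.insert(0, "site_type", series.site_type)
    df.insert(0, "site_id", series.site_id)
    df.index.name = "datetime"
    df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%SZ")


def read_site_csv(path: str | Path) -> HourlySiteSeries:
    """Read one site CSV written in the package dialect."""
    df = pd.read_csv(path, parse_dates=["datetime"], index_col="datetime")
    df.index = df.index.tz_localize(None)
    df.index.name = None
    site_id = str(df["site_id"].iloc[0])
    site_type = str(df["site_type"].iloc[0])
    zone = str(df["zone"].iloc[0])
    df = df.drop(columns=["site_id", "site_type", "zone"])
    return HourlySiteSeries(site_id=site_id, site_type=site_type, zone=zone, data=df)


# ---------------------------------------------------------------------------
# Validity filters
# ---------------------------------------------------------------------------

def validate_days(series: HourlySiteSeries, pollutant: str) -> pd.DataFrame:
    """Per-calendar-day availability and validity flags for one pollutant.

    A day is valid iff strictly more than 75% of its 24 hours are
    non-missing, so 18/24 (exactly 75%) is invalid and 19/24 is valid.
    Days are delimited in UTC.  Returns a frame indexed by date with
    columns ``hours_present``, ``fraction`` and ``valid``.
    """
    values = series.pollutant(pollutant)
    present = values.notna().groupby(values.index.date).sum()
    out = pd.DataFrame(
        {
            "hours_present": present.astype(int),
            "fraction": present / 24.0,
        }
    )
    out.index = pd.to_datetime(out.index)
    out["valid"] = out["fraction"] > DAY_VALIDITY_THRESHOLD
    return out


@dataclass
class QcReport:
    """Per-site, per-pollutant completeness summary and inclusion decision."""

    site_id: str
    pollutant: str
    daily: pd.DataFrame  # output of validate_days
    n_valid_days: int
    n_window_days: int
    valid_day_fraction: float
    included: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "pollutant": self.pollutant,
            "n_valid_days": self.n_valid_days,
            "n_window_days": self.n_window_days,
            "valid_day_fraction": self.valid_day_fraction,
            "included": self.included,
            "reason": self.reason,
        }


def qc_site(
    series: HourlySiteSeries,
    pollutant: str,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> QcReport:
    """Assess one site/pollutant against the completeness rules.

    ``window`` is a (start, end) date pair (end exclusive); defaults to
    the series' own span.  The site is included iff the fraction of valid
    days within the window strictly exceeds 80%.
    """
    daily = validate_days(series, pollutant)
    if window is None:
        start, end = series.index.min().normalize(), series.index.max().normalize()
        end = end + pd.Timedelta(days=1)
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end <= start:
        raise ValueError("empty study window")
    days = pd.date_range(start.normalize(), end.normalize(), freq="D", inclusive="left")
    in_window = daily.reindex(days)
    n_window = len(days)
    n_valid = int(in_window["valid"].fillna(False).sum())
    frac = n_valid / n_window
    included = frac > SITE_INCLUSION_THRESHOLD
    reason = (
        "valid-day fraction {:.4f} > {:.2f}".format(frac, SITE_INCLUSION_THRESHOLD)
        if included
        else "valid-day fraction {:.4f} <= {:.2f}".format(frac, SITE_INCLUSION_THRESHOLD)
    )
    return QcReport(
        site_id=series.site_id,
        pollutant=pollutant,
        daily=daily,
        n_valid_days=n_valid,
        n_window_days=n_window,
        valid_day_fraction=frac,
        included=included,
        reason=reason,
    )


def filter_sites(reports: list[QcReport]) -> list[str]:
    """Site ids whose reports pass inclusion (per pollutant, strict >80%)."""
    if not reports:
        raise ValueError("no QC reports supplied")
    return [r.site_id for r in reports if r.included]


def write_qc_reports(reports: list[QcReport], csv_path: str | Path, json_path: str | Path | None = None) -> None:
    rows = [r.to_dict() for r in reports]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2, default=float))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_group(
    series_list: list[HourlySiteSeries],
    columns: tuple[str, ...] = POLLUTANTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly arithmetic mean across sites, ignoring missing values.

    Returns ``(mean, count)`` frames on the union hourly grid; an hour
    missing at every site is missing in the aggregate (count 0).
    """
    if not series_list:
        raise ValueError("empty site group: no data for this zone/site-type")
    frames = [s.data for s in series_list]
    start = min(f.index.min() for f in frames)
    end = max(f.index.max() for f in frames)
    grid = pd.date_range(start, end, freq="h")
    cols = [c for c in columns if all(c in f.columns for f in frames)]
    stacked = np.stack(
        [f.reindex(grid)[cols].to_numpy(dtype=float) for f in frames], axis=0
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN hours
        mean = np.nanmean(stacked, axis=0)
    count = np.sum(~np.isnan(stacked), axis=0)
    mean_df = pd.DataFrame(mean, index=grid, columns=cols)
    count_df = pd.DataFrame(count, index=grid, columns=cols)
    return mean_df, count_df


def aggregate_hourly_series(series_map: dict[str, pd.Series]) -> tuple[pd.Series, pd.Series]:
    """Masked hourly mean of plain per-site series (e.g. deweathered)."""
    if not series_map:
        raise ValueError("empty site group")
    df = pd.DataFrame(series_map)
    return df.mean(axis=1, skipna=True), df.notna().sum(axis=1)
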