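import numpy as np
import pandas as pd
import pytest

from aqcausal.ingest import MET_COLUMNS, HourlySiteSeries
from aqcausal.synth import SimConfig


@pytest.fixture
def tiny_config():
    """A few-month, few-site scenario for fast structural tests."""
    return SimConfig(
        n_treated_sites=1,
        n_donor_cities=3,
        start="2018-05-01",
        end="2018-11-01",
        effect_start="2018-09-03",
        missing_rate=0.0,
        pollutants=("no2",),
        seed=11,
    )


@pytest.fixture
def flat_series():
    """A fully complete constant-valued hourly site record (90 days)."""
    grid = pd.date_range("2019-01-01", periods=24 * 90, freq="h")
    data = pd.DataFrame({"no2": 30.0, "nox": 60.0, "pm25": 10.0}, index=grid)
    for c in MET_COLUMNS:
        data[c] = 1.0
    return HourlySiteSeries(site_id="S1", site_type="urban_background", zone="central", data=data)


def make_series(values: dict, start="2019-01-01", site_id="S1", **kwargs):
    """Build an HourlySiteSeries from per-pollutant value arrays."""
    n = len(next(iter(values.values())))
    grid = pd.date_range(start, periods=n, freq="h")
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()}, index=grid)
    for c in MET_COLUMNS:
        data[c] = 1.0
    defaults = dict(site_type="urban_background", zone="central")
    defaults.update(kwargs)
    return HourlySiteSeries(site_id=site_id, data=data, **defaults)
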