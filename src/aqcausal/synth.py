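"""Synthetic multi-city hourly air-quality panels with known ground truth.

Emulates the data-generating structure that weather normalization and
synthetic-control estimation assume: one treated region whose monitoring
sites (urban background and urban traffic) share a common meteorology, a
donor pool of unaffected cities each with its own weather, and a step
policy intervention of configurable relative size.

Each site's hourly concentration is built multiplicatively:

    C(t) = E(t) * policy(t) * M(t) * exp(eps_t)

where E(t) is the emission component (baseline x seasonal x diurnal x
weekday x slow trend), policy(t) is 1 before the intervention and 1-delta
after it for treated sites (1 always for donors), M(t) is a mean-one
meteorological modulation (dilution by wind speed and boundary-layer
height) and eps_t is Gaussian on the log scale, i.e. lognormal
multiplicative noise.  The emission component times the policy multiplier
is recorded as ground truth so downstream stages can be scored against a
known answer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import MET_COLUMNS, POLLUTANTS, HourlySiteSeries

SITE_TYPES = ("urban_background", "urban_traffic")

# Diel emission cycle with morning and evening traffic peaks; normalized to
# mean 1 at config validation time.
_DEFAULT_DIURNAL = np.array(
    [
        0.55, 0.45, 0.40, 0.40, 0.50, 0.70,
        1.10, 1.55, 1.70, 1.45, 1.25, 1.15,
        1.10, 1.10, 1.15, 1.25, 1.45, 1.65,
        1.55, 1.30, 1.05, 0.90, 0.75, 0.65,
    ]
)

# Mon..Sun; weekdays busier than weekends.
_DEFAULT_WEEKDAY = np.array([1.04, 1.05, 1.05, 1.05, 1.06, 0.92, 0.83])


def _default_baselines() -> dict:
    # Annual-mean concentrations (ug m-3) typical of a large UK city,
    # urban background vs roadside.
    return {
        "urban_background": {"no2": 28.0, "nox": 45.0, "pm25": 11.0},
        "urban_traffic": {"no2": 55.0, "nox": 130.0, "pm25": 14.0},
    }


@dataclass
class SimConfig:
    """Scenario definition for the synthetic panel generator.

    Defaults describe a two-year hourly study window around an
    intervention, with multiplicative lognormal noise (sigma 0.3),
    moderate meteorological coupling and a 15% step reduction at treated
    sites from the intervention date onward.
    """

    n_treated_sites: int = 3  # per site type, in the treated region
    n_donor_cities: int = 8  # each contributes one site per site type
    start: pd.Timestamp = pd.Timestamp("2018-03-08 00:00")
    end: pd.Timestamp = pd.Timestamp("2020-03-08 00:00")  # exclusive
    baseline_concentration: dict = field(default_factory=_default_baselines)
    seasonal_amplitude: float = 0.25
    diurnal_profile: np.ndarray = field(
        default_factory=lambda: _DEFAULT_DIURNAL.copy()
    )
    weekday_factors: np.ndarray = field(
        default_factory=lambda: _DEFAULT_WEEKDAY.copy()
    )
    annual_trend: float = -0.03  # fractional change per year
    k_ws: float = 0.12  # dilution per m/s of wind speed
    k_blh: float = 0.30  # boundary-layer height exponent
    noise_sd: float = 0.3  # lognormal sigma
    effect_size: float = 0.15  # fractional reduction delta in [0, 1)
    effect_start: pd.Timestamp = pd.Timestamp("2019-04-08 00:00")
    effect_site_types: tuple = SITE_TYPES  # site types receiving the effect
    effect_hours: tuple | None = None  # None = all hours; else e.g. (6,7,8,9)
    missing_rate: float = 0.02
    site_scale_sd: float = 0.12  # lognormal spread of per-site baselines
    met_noise_scale: float = 1.0  # multiplies all meteorological noise SDs
    pollutants: tuple = POLLUTANTS
    seed: int = 0

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        self.effect_start = pd.Timestamp(self.effect_start)
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if not (self.start <= self.effect_start <= self.end):
            raise ValueError("effect_start must lie within [start, end]")
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        self.diurnal_profile = np.asarray(self.diurnal_profile, dtype=float)
        self.weekday_factors = np.asarray(self.weekday_factors, dtype=float)
        if self.diurnal_profile.shape != (24,):
            raise ValueError("diurnal_profile must have 24 entries")
        if self.weekday_factors.shape != (7,):
            raise ValueError("weekday_factors must have 7 entries")
        if np.any(self.diurnal_profile <= 0) or np.any(self.weekday_factors <= 0):
            raise ValueError("profile factors must be strictly positive")
        # Normalize so baselines are interpretable as period means.
        self.diurnal_profile = self.diurnal_profile / self.diurnal_profile.mean()
        self.weekday_factors = self.weekday_factors / self.weekday_factors.mean()

    @property
    def grid(self) -> pd.DatetimeIndex:
        """Hourly timestamp grid [start, end)."""
        return pd.date_range(self.start, self.end, freq="h", inclusive="left")


@dataclass
class GroundTruth:
    """Per-site truth: emission component and policy multiplier."""

    site_id: str
    emission: pd.DataFrame  # one column per pollutant, E(t) in ug m-3
    policy: pd.Series  # multiplier, 1 before effect / (1-delta) after

    def truth(self, pollutant: str) -> pd.Series:
        """Noise- and weather-free concentration E(t) * policy(t)."""
        return self.emission[pollutant] * self.policy


def _site_rng(master_seed: int, site_id: str, stream: str = "") -> np.random.Generator:
    """Derive a per-site RNG stream by stable hashing of (seed, site id).

    Adding sites to a scenario never perturbs existing series because each
    stream depends only on its own identifiers.
    """
    key = zlib.crc32(f"{site_id}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = 0.8) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation `sd`."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    z = rng.standard_normal(n)
    x[0] = sd * z[0]
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov_sd * z[i]
    return x


def met_template(grid: pd.DatetimeIndex) -> pd.DataFrame:
    """Deterministic seasonal + diurnal meteorology template on `grid`."""
    doy = grid.dayofyear.to_numpy(float)
    hour = grid.hour.to_numpy(float)
    season = np.cos(2 * np.pi * (doy - 196.0) / 365.25)  # +1 mid-July
    day_bell = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)

    temp = 10.5 + 7.0 * season + 3.5 * (day_bell - 0.41)
    rh = 78.0 - 8.0 * season - 12.0 * (day_bell - 0.41)
    ws = 4.2 - 0.8 * season
    wd = np.full(len(grid), 225.0)
    ssr = 160.0 * (1.0 + 0.85 * season) * day_bell
    precip = np.zeros(len(grid))
    blh = 350.0 + 120.0 * season + 900.0 * (1.0 + 0.4 * season) * day_bell
    tcc = np.full(len(grid), 0.62)
    sp = np.full(len(grid), 1013.0)
    return pd.DataFrame(
        {
            "temp_c": temp,
            "rh_pct": rh,
            "ws_ms": ws,
            "wd_deg": wd,
            "ssr": ssr,
            "precip_mm": precip,
            "blh_m": blh,
            "tcc": tcc,
            "sp_hpa": sp,
        },
        index=grid,
    )


def generate_met(config: SimConfig, site_seed: int) -> pd.DataFrame:
    """Generate one city's hourly meteorology table.

    Deterministic seasonal/diurnal structure plus AR(1) noise with lag-1
    autocorrelation 0.8, scaled by ``config.met_noise_scale``.  Physical
    bounds are enforced after noise is added: wind speed >= 0, boundary
    layer height > 0, cloud cover in [0, 1], wind direction in [0, 360).
    """
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x4D45, site_seed]))
    n = len(grid)
    s = config.met_noise_scale
    out = met_template(grid)

    out["temp_c"] = out["temp_c"] + _ar1(rng, n, 3.0 * s)
    out["rh_pct"] = np.clip(out["rh_pct"] + _ar1(rng, n, 10.0 * s), 5.0, 100.0)
    out["ws_ms"] = np.clip(out["ws_ms"] + _ar1(rng, n, 2.0 * s), 0.0, None)
    out["wd_deg"] = np.mod(out["wd_deg"] + _ar1(rng, n, 60.0 * s), 360.0)
    out["ssr"] = np.clip(out["ssr"] * (1.0 + _ar1(rng, n, 0.35 * s)), 0.0, None)
    out["precip_mm"] = np.clip(_ar1(rng, n, 0.6 * s) - 0.3 * s, 0.0, None)
    out["blh_m"] = np.clip(out["blh_m"] * np.exp(_ar1(rng, n, 0.35 * s)), 50.0, None)
    out["tcc"] = np.clip(out["tcc"] + _ar1(rng, n, 0.25 * s), 0.0, 1.0)
    out["sp_hpa"] = out["sp_hpa"] + _ar1(rng, n, 8.0 * s)
    return out


def emission_component(
    config: SimConfig, site_type: str, pollutant: str, scale: float = 1.0
) -> pd.Series:
    """Deterministic emission component E(t) for one site/pollutant."""
    grid = config.grid
    base = config.baseline_concentration[site_type][pollutant] * scale
    doy = grid.dayofyear.to_numpy(float)
    season = 1.0 + config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
    diurnal = config.diurnal_profile[grid.hour.to_numpy()]
    weekday = config.weekday_factors[grid.dayofweek.to_numpy()]
    years = (grid - config.start).total_seconds().to_numpy() / (365.25 * 24 * 3600)
    trend = 1.0 + config.annual_trend * years
    return pd.Series(base * season * diurnal * weekday * trend, index=grid)


def _policy_multiplier(config: SimConfig, treated: bool, site_type: str) -> pd.Series:
    grid = config.grid
    mult = np.ones(len(grid))
    if treated and site_type in config.effect_site_types and config.effect_size > 0:
        post = np.asarray(grid >= config.effect_start)
        if config.effect_hours is not None:
            post &= np.isin(grid.hour.to_numpy(), np.asarray(config.effect_hours))
        mult[post] = 1.0 - config.effect_size
    return pd.Series(mult, index=grid)


def met_modulation(config: SimConfig, met: pd.DataFrame) -> pd.Series:
    """Mean-one meteorological modulation M(t) from wind speed and BLH."""
    ws = met["ws_ms"].to_numpy()
    blh = met["blh_m"].to_numpy()
    blh_ref = blh.mean()
    m = np.exp(-config.k_ws * ws) * (blh_ref / blh) ** config.k_blh
    m = m / m.mean()
    return pd.Series(m, index=met.index)


def generate_site_series(
    config: SimConfig,
    met: pd.DataFrame,
    treated: bool,
    site_id: str,
    site_type: str = "urban_background",
    zone: str = "central",
    baseline_scale: float = 1.0,
    apply_missing: bool = True,
) -> tuple[HourlySiteSeries, GroundTruth]:
    """Generate one site's hourly pollutant series plus its ground truth.

    The observed concentration is E(t) * policy(t) * M(t) * exp(eps) with
    per-pollutant independent lognormal noise; the ground truth records
    E(t) * policy(t) only, i.e. what a perfect weather normalization of a
    noise-free record would recover.
    """
    if not met.index.equals(config.grid):
        raise ValueError("met table must cover the configured hourly grid")
    mod = met_modulation(config, met)
    policy = _policy_multiplier(config, treated, site_type)

    conc = {}
    emissions = {}
    for pol in config.pollutants:
        rng = _site_rng(config.seed, site_id, f"noise/{pol}")
        e = emission_component(config, site_type, pol, scale=baseline_scale)
        eps = (
            rng.standard_normal(len(e)) * config.noise_sd
            if config.noise_sd > 0
            else np.zeros(len(e))
        )
        c = e * policy * mod * np.exp(eps)
        if apply_missing and config.missing_rate > 0:
            miss_rng = _site_rng(config.seed, site_id, f"missing/{pol}")
            drop = miss_rng.random(len(c)) < config.missing_rate
            c = c.mask(drop)
        conc[pol] = c
        emissions[pol] = e

    data = pd.DataFrame(conc)
    data[list(MET_COLUMNS)] = met
    series = HourlySiteSeries(site_id=site_id, site_type=site_type, zone=zone, data=data)
    truth = GroundTruth(site_id=site_id, emission=pd.DataFrame(emissions), policy=policy)
    return series, truth


def generate_panel(
    config: SimConfig,
) -> tuple[list[HourlySiteSeries], dict[str, GroundTruth]]:
    """Generate the full panel: treated-region sites plus donor cities.

    Treated sites share the treated region's meteorology draw; each donor
    city gets an independent draw (so weather normalization is actually
    needed to compare them).  Donor cities contribute one site per site
    type, flagged with zone ``donor:<city>``.
    """
    if config.n_donor_cities < 2:
        raise ValueError("need at least 2 donor cities for a donor pool")
    series: list[HourlySiteSeries] = []
    truths: dict[str, GroundTruth] = {}

    treated_met = generate_met(config, site_seed=zlib.crc32(b"region/treated"))
    for site_type in SITE_TYPES:
        code = "UB" if site_type == "urban_background" else "UT"
        for i in range(config.n_treated_sites):
            site_id = f"LON_{code}{i + 1:02d}"
            scale = _site_scale(config, site_id)
            s, t = generate_site_series(
                config, treated_met, True, site_id, site_type, "central", scale
            )
            series.append(s)
            truths[site_id] = t

    for j in range(config.n_donor_cities):
        city = f"CITY{j + 1:02d}"
        city_met = generate_met(config, site_seed=zlib.crc32(f"region/{city}".encode()))
        for site_type in SITE_TYPES:
            code = "UB" if site_type == "urban_background" else "UT"
            site_id = f"{city}_{code}01"
            scale = _site_scale(config, site_id)
            s, t = generate_site_series(
                config, city_met, False, site_id, site_type, f"donor:{city}", scale
            )
            series.append(s)
            truths[site_id] = t
    return series, truths


def _site_scale(config: SimConfig, site_id: str) -> float:
    if config.site_scale_sd == 0:
        return 1.0
    rng = _site_rng(config.seed, site_id, "scale")
    return float(np.exp(rng.standard_normal() * config.site_scale_sd))


def reference_site(
    seed: int = 1, config: SimConfig | None = None
) -> tuple[SimConfig, HourlySiteSeries, GroundTruth]:
    """One treated urban-traffic site under the default two-year scenario.

    The canonical single-site record used for model-quality and
    ground-truth-recovery checks: the treated region's meteorology draw
    with an urban-traffic site generated on top of it.
    """
    cfg = config if config is not None else SimConfig(seed=seed)
    met = generate_met(cfg, site_seed=zlib.crc32(b"region/treated"))
    series, truth = generate_site_series(
        cfg, met, treated=True, site_id="LON_UT01", site_type="urban_traffic"
    )
    return cfg, series, truth


def with_effect_size(config: SimConfig, effect_size: float) -> SimConfig:
    """Same scenario with a different injected effect (donors unaffected)."""
    return replace(config, effect_size=effect_size)


# ---------------------------------------------------------------------------
# Weekly-scale panel generator
# ---------------------------------------------------------------------------

def simulate_weekly_panel(
    n_donors: int = 15,
    n_pre: int = 40,
    n_post: int = 12,
    effect_size: float = 0.15,
    noise_sd: float = 0.025,
    baseline: float = 40.0,
    seasonal_amplitude: float = 0.2,
    annual_trend: float = -0.03,
    loading_sd: float = 0.15,
    level_sd: float = 0.15,
    seed: int = 0,
    effect_on_treated: bool = True,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Simulate weekly weather-normalized outcomes directly.

    Emulates what the hourly pipeline delivers to the synthetic-control
    stage: weekly mean concentrations whose meteorological variation has
    already been removed, leaving a shared seasonal cycle, a slow downward
    trend, unit-specific levels and loadings, and small residual noise
    (``noise_sd`` defaults to the weekly-scale remnant of hourly lognormal
    noise with sigma 0.3 averaged over a 168-hour week).

    The treated unit is a convex-combination-like member of the donor
    population, with a step reduction of ``effect_size`` from week 0 on.

    Returns ``(treated, donors, truth)`` where ``truth`` is the treated
    unit's no-intervention trajectory.
    """
    rng = np.random.default_rng(seed)
    weeks = np.arange(-n_pre, n_post)
    t = weeks.astype(float)
    season = np.cos(2 * np.pi * (t - 40.0) / 52.18)
    trend = 1.0 + annual_trend * t / 52.18

    def unit(level: float, loading: float) -> np.ndarray:
        shape = (1.0 + loading * seasonal_amplitude * season) * trend
        return level * baseline * shape

    levels = np.exp(rng.standard_normal(n_donors) * level_sd)
    loadings = 1.0 + rng.standard_normal(n_donors) * loading_sd
    donors = {}
    for j in range(n_donors):
        y = unit(levels[j], loadings[j]) * np.exp(
            rng.standard_normal(len(t)) * noise_sd
        )
        donors[f"D{j + 1:02d}"] = y
    donors = pd.DataFrame(donors, index=weeks)

    # Treated unit: population-typical level/loading so the donor convex
    # hull can reproduce its pre-period.
    lvl = float(np.exp(rng.standard_normal() * level_sd * 0.5))
    ld = 1.0 + float(rng.standard_normal()) * loading_sd * 0.5
    base_path = unit(lvl, ld)
    truth = pd.Series(base_path, index=weeks)
    mult = np.ones(len(t))
    if effect_on_treated and effect_size > 0:
        mult[weeks >= 0] = 1.0 - effect_size
    treated = pd.Series(
        base_path * mult * np.exp(rng.standard_normal(len(t)) * noise_sd),
        index=weeks,
    )
    return treated, donors, truth
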