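"""End-to-end orchestration: simulate -> QC -> deweather -> ASCM -> effects.

A single :class:`RunConfig` drives every stage; a JSON run manifest
(config hash, seeds, library versions) makes any run reproducible.  The
deweathering stage dominates runtime, so its per-site outputs are cached
on disk keyed by the configuration hash and reused when only downstream
settings change.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ascm import WeeklyPanel, fit_ascm, screen_donors, to_weekly
from .deweather import deweather_site
from .effects import average_effect
from .ingest import POLLUTANTS, HourlySiteSeries, qc_site
from .synth import SITE_TYPES, SimConfig, generate_panel


@dataclass
class RunConfig:
    """Everything needed to reproduce one evaluation run."""

    sim: dict = field(default_factory=dict)  # SimConfig overrides
    pollutants: tuple = POLLUTANTS
    windows_months: tuple = (1, 3)
    deweather_n_trees: int = 300
    deweather_min_node_size: int = 5
    n_resamples: int = 150
    window_half_width: int = 14
    alpha: float = 0.05
    ridge_lambda: float | None = None  # None = leave-one-donor-out CV
    seed: int = 0
    blackout: tuple | None = None  # (start, end) interval the window must avoid

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def validate(self) -> None:
        sim = self.sim_config()
        if self.blackout is not None:
            b0, b1 = (pd.Timestamp(t) for t in self.blackout)
            if b0 < sim.end and b1 > sim.start:
                raise ValueError(
                    "study window overlaps the configured blackout interval"
                )

    def canonical(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=str, sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stream_seed(master: int, *parts: str) -> int:
    key = zlib.crc32("/".join(parts).encode())
    return int(np.random.SeedSequence([master, key]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage in order and return the results bundle.

    Returns a dict with QC reports, deweather diagnostics, the fitted
    synthetic controls and windowed effect summaries per
    (site type, pollutant), plus the manifest.  With ``out_dir`` set,
    intermediate artifacts, a tidy results CSV and the manifest are
    written there; cached deweathered series keyed by the relevant part
    of the config hash are reused.
    """
    config.validate()
    sim = config.sim_config()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = {"stage": "simulate"}
    try:
        series, truths = generate_panel(sim)
        stage["stage"] = "qc"
        qc_reports = []
        included: dict[str, list[HourlySiteSeries]] = {}
        window = (sim.start, sim.end)
        for s in series:
            for pol in config.pollutants:
                rep = qc_site(s, pol, window)
                qc_reports.append(rep)
                if rep.included:
                    included.setdefault(pol, []).append(s)

        stage["stage"] = "deweather"
        wn, diagnostics = _deweather_stage(config, included, out)

        stage["stage"] = "ascm"
        results = {}
        for pol in config.pollutants:
            for site_type in SITE_TYPES:
                key = (site_type, pol)
                built = _build_panel(wn, pol, site_type, sim)
                if built is None:
                    continue
                panel, screening = built
                fit = fit_ascm(panel, lam=config.ridge_lambda, alpha=config.alpha)
                summaries = {}
                for months in config.windows_months:
                    try:
                        summaries[months] = average_effect(fit, months)
                    except ValueError:
                        continue
                results[key] = {
                    "fit": fit,
                    "screening": screening,
                    "summaries": summaries,
                }

        stage["stage"] = "report"
        manifest = {
            "config": config.canonical(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": _versions(),
        }
        bundle = {
            "qc": qc_reports,
            "deweather_diagnostics": diagnostics,
            "wn": wn,
            "results": results,
            "truths": truths,
            "manifest": manifest,
        }
        if out is not None:
            _write_outputs(bundle, out)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage['stage']!r}: {exc}") from exc


def _deweather_stage(config: RunConfig, included: dict, out: Path | None):
    """Deweather every included site/pollutant, using the on-disk cache."""
    cache_key = _deweather_hash(config)
    cache_dir = out / f"wn_cache_{cache_key}" if out is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(exist_ok=True)
    wn: dict[str, dict[str, pd.Series]] = {}
    diagnostics = {}
    for pol, sites in included.items():
        wn[pol] = {}
        for s in sites:
            cache_file = (
                cache_dir / f"{s.site_id}_{pol}.csv" if cache_dir is not None else None
            )
            if cache_file is not None and cache_file.exists():
                cached = pd.read_csv(
                    cache_file,
                    parse_dates=["datetime"],
                    index_col="datetime",
                    float_precision="round_trip",
                )
                wn[pol][s.site_id] = cached["value_wn"]
                continue
            seed = _stream_seed(config.seed, "deweather", s.site_id, pol)
            series_wn, model = deweather_site(
                s,
                pol,
                seed=seed,
                n_resamples=config.n_resamples,
                window_half_width=config.window_half_width,
                n_trees=config.deweather_n_trees,
                min_node_size=config.deweather_min_node_size,
            )
            wn[pol][s.site_id] = series_wn
            diagnostics[(s.site_id, pol)] = model.diagnostics()
            if cache_file is not None:
                df = series_wn.rename("value_wn").to_frame()
                df.index.name = "datetime"
                df.to_csv(cache_file, float_format="%.17g")
    return wn, diagnostics


def _deweather_hash(config: RunConfig) -> str:
    relevant = {
        "sim": config.sim,
        "seed": config.seed,
        "n_resamples": config.n_resamples,
        "window_half_width": config.window_half_width,
        "n_trees": config.deweather_n_trees,
        "min_node_size": config.deweather_min_node_size,
    }
    return hashlib.sha256(
        json.dumps(relevant, default=str, sort_keys=True).encode()
    ).hexdigest()[:12]


def _build_panel(wn: dict, pol: str, site_type: str, sim: SimConfig):
    """Weekly panel for one site type/pollutant from deweathered series."""
    per_site = wn.get(pol, {})
    code = "UB" if site_type == "urban_background" else "UT"
    treated_sites = {k: v for k, v in per_site.items() if k.startswith(f"LON_{code}")}
    donor_sites = {
        k: v
        for k, v in per_site.items()
        if k.startswith("CITY") and k.endswith(f"{code}01")
    }
    if not treated_sites or len(donor_sites) < 2:
        return None
    treated_hourly = pd.DataFrame(treated_sites).mean(axis=1)
    treated_weekly = to_weekly(treated_hourly, sim.effect_start)
    donors_weekly = {
        k.split("_")[0]: to_weekly(v, sim.effect_start) for k, v in donor_sites.items()
    }
    try:
        screening = screen_donors(donors_weekly, treated_weekly)
        kept = {k: donors_weekly[k] for k in screening.retained}
    except Exception:
        screening = None
        kept = donors_weekly
    pre_ok = treated_weekly.index[treated_weekly.notna() & (treated_weekly.index < 0)]
    panel = WeeklyPanel(
        treated=treated_weekly.loc[treated_weekly.index >= pre_ok.min()].dropna(),
        donors=pd.DataFrame(kept).dropna(),
        intervention=sim.effect_start,
    )
    return panel, screening


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "aqcausal": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


def _write_outputs(bundle: dict, out: Path) -> None:
    rows = []
    for (site_type, pol), res in bundle["results"].items():
        for months, summary in res["summaries"].items():
            row = {"site_type": site_type, "pollutant": pol}
            row.update(summary.to_dict())
            rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(out / "effect_summaries.csv", index=False)
    fits = {
        f"{site_type}/{pol}": res["fit"].to_dict()
        for (site_type, pol), res in bundle["results"].items()
    }
    (out / "ascm_fits.json").write_text(json.dumps(fits, indent=2))
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    qc_rows = [r.to_dict() for r in bundle["qc"]]
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.csv", index=False)
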