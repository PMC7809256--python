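"""End-to-end orchestration: simulate -> decompose -> metrics -> events -> maps.

``run_full_analysis`` drives the whole chain from an :class:`AnalysisConfig`
and writes every artifact (NetCDF grids, CSV tables, the bloom mask and a
JSON manifest with content checksums) under one output directory.  The same
configuration and seed always reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import x11_decompose
from .events import (DEFAULT_LAGS, PhaseLabel, aggregate_composite,
                     analysis_window_mask, bin_relation, classify_intervals,
                     composite_about_crossing, find_zero_crossings,
                     last_persistent_crossing)
from .grid_io import ForcingBundle, read_bundle, write_bundle
from .maps import (bloom_mask, seasonal_climatology, sign_agreement_map,
                   write_mask_ascii)
from .metrics import forward_derivative, net_growth_rate
from .synthetic import SimConfig, simulate_dataset
from .timeaxis import TimeAxis

logger = logging.getLogger("bloomflux")

__all__ = ["AnalysisConfig", "run_full_analysis", "analysis_config_from_file"]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    mode: str = "synthetic"              # "synthetic" | "files"
    sim: SimConfig | None = None         # required in synthetic mode
    bundle_path: str | None = None       # required in file mode
    bloom_threshold: float = 0.65        # mg Chl m-3 on the spring climatology
    driver: str = "dnhf"                 # "dnhf" | "dws"
    n_bins: int = 9
    min_count: int = 10
    decompose: bool = True
    out_dir: str = "bloomflux_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.sim is None:
            raise ValueError("synthetic mode requires a [simulation] section")
        if self.mode == "files" and not self.bundle_path:
            raise ValueError("file mode requires bundle_path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fresh_path(path: Path) -> Path:
    """Never overwrite silently: version the name if the target exists."""
    if not path.exists():
        return path
    for k in range(2, 1000):
        candidate = path.with_name(f"{path.stem}-v{k}{path.suffix}")
        if not candidate.exists():
            return candidate
    raise RuntimeError(f"too many versions of {path}")


def _grid_to_netcdf(fields: list, path: Path) -> Path:
    import xarray as xr
    ds = xr.Dataset({f.name: f.to_dataarray() for f in fields})
    ds.to_netcdf(path, engine="scipy")
    ds.close()
    return path


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete pipeline; returns the manifest dictionary.

    Stages: (1) obtain the forcing bundle (simulate or read), (2) X-11
    decomposition of SChl, (3) derived interval series (net growth, dNHF/dt,
    dWS/dt), (4) lag composite about the last persistent zero crossing and
    bin-averaged growth-driver relations per phase over the bloom region,
    (5) climatologies, bloom mask and sign-agreement maps.  A stage failure
    aborts the run with the stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def record(path: Path) -> None:
        artifacts[path.name] = _sha256(path)

    stage = "input"
    try:
        if config.mode == "synthetic":
            bundle = simulate_dataset(config.sim)
            path = _fresh_path(out / "forcing_bundle.nc")
            write_bundle(bundle, path)
            record(path)
        else:
            bundle = read_bundle(config.bundle_path)
        axis = bundle.axis
        nlat, nlon = bundle.lats.size, bundle.lons.size
        npix = nlat * nlon
        counts["pixels"] = npix
        counts["time_steps"] = axis.n_steps
        logger.info("input: %d pixels x %d steps", npix, axis.n_steps)

        stage = "decomposition"
        if config.decompose:
            schl_flat = bundle.schl.data.reshape(axis.n_steps, npix)
            dec = x11_decompose(schl_flat, p=config.sim.steps_per_year
                                if config.sim else 46)
            from .grid_io import GridField
            comp_fields = []
            for name, comp in (("schl_trend", dec.trend),
                               ("schl_seasonal", dec.seasonal),
                               ("schl_isv", dec.irregular)):
                comp_fields.append(GridField(name, bundle.schl.units, bundle.lats,
                                             bundle.lons, axis,
                                             comp.reshape(axis.n_steps, nlat, nlon)))
            path = _fresh_path(out / "decomposition.nc")
            _grid_to_netcdf(comp_fields, path)
            record(path)

        stage = "metrics"
        growth = net_growth_rate(bundle.schl.data)
        dnhf = forward_derivative(bundle.nhf.data)
        dws = forward_derivative(bundle.ws.data)
        from .grid_io import GridField
        interval_axis = axis.slice_steps(slice(0, axis.n_steps - 1))
        derived_fields = [
            GridField("net_growth", "day-1", bundle.lats, bundle.lons,
                      interval_axis, growth),
            GridField("dnhf_dt", "W m-2 day-1", bundle.lats, bundle.lons,
                      interval_axis, dnhf),
            GridField("dws_dt", "N m-2 day-1", bundle.lats, bundle.lons,
                      interval_axis, dws),
        ]
        path = _fresh_path(out / "derived_series.nc")
        _grid_to_netcdf(derived_fields, path)
        record(path)

        stage = "maps"
        clim_w = seasonal_climatology(bundle.schl, "winter")
        clim_s = seasonal_climatology(bundle.schl, "spring")
        mask = bloom_mask(clim_s, config.bloom_threshold)
        counts["bloom_pixels"] = mask.n_pixels
        logger.info("bloom mask: %d of %d pixels", mask.n_pixels, npix)
        agreement = []
        for season in ("winter", "spring"):
            for driver_kind, drv in (("nhf", dnhf), ("ws", dws)):
                agreement.append(sign_agreement_map(growth, drv, axis, season,
                                                    bundle.lats, bundle.lons,
                                                    driver_kind))
        path = _fresh_path(out / "maps.nc")
        _grid_to_netcdf([clim_w, clim_s] + agreement, path)
        record(path)
        path = _fresh_path(out / "bloom_mask.txt")
        write_mask_ascii(mask, path)
        record(path)

        stage = "events"
        pix_mask = mask.values.reshape(npix)
        use_pixels = np.nonzero(pix_mask)[0] if pix_mask.any() else np.arange(npix)
        nhf_flat = bundle.nhf.data.reshape(axis.n_steps, npix)
        growth_flat = growth.reshape(axis.n_steps - 1, npix)
        dnhf_flat = dnhf.reshape(axis.n_steps - 1, npix)
        dws_flat = dws.reshape(axis.n_steps - 1, npix)
        contribs = []
        n_events = 0
        phase_rows = {ph: {"g": [], "d": []} for ph in
                      ("winter", "transition", "spring")}
        window = analysis_window_mask(axis)
        interval_window = window[:-1] & window[1:]
        for k in use_pixels:
            events = find_zero_crossings(nhf_flat[:, k], axis, pixel=int(k))
            n_events += len(events)
            for year in np.unique([e.year for e in events]) if events else []:
                ev = last_persistent_crossing([e for e in events if e.year == year])
                if ev is not None:
                    contribs.append(composite_about_crossing(growth_flat[:, k], ev, axis))
            labels = classify_intervals(nhf_flat[:, k])
            drv = dnhf_flat[:, k] if config.driver == "dnhf" else dws_flat[:, k]
            for ph in phase_rows:
                wanted = {"winter": (PhaseLabel.WINTER_UNSTABLE,),
                          "transition": (PhaseLabel.TRANSITION_SHUTDOWN,
                                         PhaseLabel.TRANSITION_RESUME),
                          "spring": (PhaseLabel.SPRING_STABLE,)}[ph]
                sel = (interval_window
                       & np.array([lab in wanted for lab in labels])
                       & np.isfinite(growth_flat[:, k]) & np.isfinite(drv))
                phase_rows[ph]["g"].append(growth_flat[sel, k])
                phase_rows[ph]["d"].append(drv[sel])
        counts["zero_crossings"] = n_events
        counts["composite_events"] = len(contribs)
        logger.info("events: %d crossings, %d composite events",
                    n_events, len(contribs))

        comp = aggregate_composite(contribs)
        path = _fresh_path(out / "composite.csv")
        pd.DataFrame({"lag_days": comp.lags_days, "mean_growth": comp.mean,
                      "std_growth": comp.std, "n": comp.count}).to_csv(path, index=False)
        record(path)

        for ph, rows in phase_rows.items():
            g = np.concatenate(rows["g"]) if rows["g"] else np.array([])
            d = np.concatenate(rows["d"]) if rows["d"] else np.array([])
            if g.size == 0:
                continue
            edges = np.linspace(*np.nanpercentile(d, [1, 99]), config.n_bins + 1)
            if edges[0] >= edges[-1]:
                continue
            which = np.digitize(d, edges) - 1
            rows_out = []
            for bi in range(config.n_bins):
                sel = (which == bi)
                rows_out.append({
                    "bin_center": 0.5 * (edges[bi] + edges[bi + 1]),
                    "mean_growth": g[sel].mean() if sel.any() else np.nan,
                    "std_growth": g[sel].std() if sel.any() else np.nan,
                    "n": int(sel.sum()),
                    "reliable": bool(sel.sum() >= config.min_count),
                })
            path = _fresh_path(out / f"binned_{ph}.csv")
            pd.DataFrame(rows_out).to_csv(path, index=False)
            record(path)

        stage = "manifest"
        manifest = {"config_mode": config.mode, "driver": config.driver,
                    "counts": counts, "artifacts": artifacts}
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def analysis_config_from_file(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig (and nested SimConfig) from TOML or YAML."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml
        raw = yaml.safe_load(path.read_text())
    elif path.suffix == ".toml":
        import tomllib
        raw = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ValueError("config file must define a mapping")
    sim = None
    if "simulation" in raw:
        sim_raw = dict(raw["simulation"])
        known = {f.name for f in dc_fields(SimConfig)}
        unknown = set(sim_raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        sim = SimConfig(**sim_raw)
    known = {f.name for f in dc_fields(AnalysisConfig)} - {"sim"}
    top = {k: v for k, v in raw.items() if k != "simulation"}
    unknown = set(top) - known
    if unknown:
        raise ValueError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
    return AnalysisConfig(sim=sim, **top)
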