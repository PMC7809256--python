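"""Gridded containers and co-registration onto the common 8-day analysis grid.

The pipeline's universal input is a :class:`ForcingBundle`: surface
chlorophyll (SChl), net heat flux (NHF) and wind stress (WS) on one shared
time axis and lat/lon grid.  This module reads and writes those bundles
(NetCDF for grids, CSV for single-pixel series) and provides the two
co-registration steps used with real products: temporal averaging of daily
atmospheric fields onto the 8-day chlorophyll grid and bilinear spatial
interpolation onto the atmospheric grid.

Gap policy: an 8-day window keeps the mean of its valid days when at least
4 of them are present, and is masked otherwise.  Bilinear stencils that
touch a masked source cell propagate the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .timeaxis import TimeAxis

__all__ = [
    "GridField",
    "ForcingBundle",
    "aggregate_time_8day",
    "regrid_bilinear",
    "extract_box_mean",
    "read_bundle",
    "write_bundle",
    "read_pixel_csv",
    "write_pixel_csv",
]

MIN_VALID_DAYS = 4  # windows with fewer valid daily values are masked

_NC_ENGINE = "scipy"  # NetCDF3 backend; available wherever scipy is


@dataclass
class GridField:
    """One gridded variable: (time, lat, lon) values with an explicit mask.

    ``mask`` is True where the value is missing.  Coordinate vectors are
    pixel centers, sorted ascending with regular spacing.
    """

    name: str
    units: str
    lats: np.ndarray
    lons: np.ndarray
    axis: TimeAxis
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise ValueError(f"field {self.name!r}: units must be non-empty")
        for vec, label in ((self.lats, "lat"), (self.lons, "lon")):
            if vec.ndim != 1 or vec.size == 0:
                raise ValueError(f"field {self.name!r}: {label} must be a 1-D vector")
            if vec.size > 1:
                d = np.diff(vec)
                if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                    raise ValueError(f"field {self.name!r}: {label} must be sorted and regular")
        expected = (self.axis.n_steps, self.lats.size, self.lons.size)
        if self.values.shape != expected:
            raise ValueError(
                f"field {self.name!r}: values shape {self.values.shape} != {expected}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError(f"field {self.name!r}: mask shape mismatch")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def data(self) -> np.ndarray:
        """Values with masked entries as NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.data,
            dims=("time", "lat", "lon"),
            coords={"time": self.axis.centers.astype("datetime64[ns]"),
                    "lat": self.lats, "lon": self.lons},
            name=self.name,
            attrs={"units": self.units, "long_name": self.name},
        )


@dataclass
class ForcingBundle:
    """Co-registered SChl / NHF / WS grids on one shared axis and grid."""

    schl: GridField
    nhf: GridField
    ws: GridField

    def __post_init__(self) -> None:
        ref = self.schl
        for f in (self.nhf, self.ws):
            if f.axis != ref.axis:
                raise ValueError(f"field {f.name!r}: time axis differs from schl")
            if not (np.array_equal(f.lats, ref.lats) and np.array_equal(f.lons, ref.lons)):
                raise ValueError(f"field {f.name!r}: spatial grid differs from schl")
        bad = (~self.schl.mask) & ~(self.schl.values > 0)
        if np.any(bad):
            t, i, j = (int(x[0]) for x in np.nonzero(bad))
            raise ValueError(f"schl must be positive where unmasked (step {t}, pixel {i},{j})")

    @property
    def axis(self) -> TimeAxis:
        return self.schl.axis

    @property
    def lats(self) -> np.ndarray:
        return self.schl.lats

    @property
    def lons(self) -> np.ndarray:
        return self.schl.lons

    def fields(self) -> dict[str, GridField]:
        return {"schl": self.schl, "nhf": self.nhf, "ws": self.ws}


# ---------------------------------------------------------------------------
# co-registration

def aggregate_time_8day(daily: GridField, target: TimeAxis) -> GridField:
    """Average a daily field onto an 8-day axis.

    Each output step is the mean of daily values whose dates fall in
    ``[center - 4 d, center + 4 d)``.  Windows with fewer than
    ``MIN_VALID_DAYS`` valid days are masked.
    """
    day_dates = daily.axis.centers
    centers = target.centers
    half = np.timedelta64(4 * 86400, "s")
    if day_dates[-1] < centers[0] - half or day_dates[0] >= centers[-1] + half:
        raise ValueError("daily series has no temporal overlap with the target axis")

    nt = target.n_steps
    out = np.zeros((nt, daily.lats.size, daily.lons.size))
    out_mask = np.ones_like(out, dtype=bool)
    valid = (~daily.mask).astype(float)
    filled = np.where(daily.mask, 0.0, daily.values)
    for t in range(nt):
        sel = (day_dates >= centers[t] - half) & (day_dates < centers[t] + half)
        if not np.any(sel):
            continue
        n_ok = valid[sel].sum(axis=0)
        s = filled[sel].sum(axis=0)
        # a window needs MIN_VALID_DAYS valid samples, or all of the samples
        # it can possibly contain (so re-averaging an 8-day series is exact)
        ok = n_ok >= min(MIN_VALID_DAYS, int(sel.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[t] = np.where(ok, s / np.maximum(n_ok, 1), 0.0)
        out_mask[t] = ~ok
    return GridField(daily.name, daily.units, daily.lats, daily.lons, target, out, out_mask)


def regrid_bilinear(src: GridField, target_lat, target_lon) -> GridField:
    """Bilinear interpolation of each time slice onto a new lat/lon grid.

    Target points outside the source bounding box are clamped to the edge
    (nearest-edge extrapolation).  If any of the four stencil cells is
    masked the output pixel is masked.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    if src.lats.size < 2 or src.lons.size < 2:
        raise ValueError("source grid needs at least 2 points per axis")

    ty = np.clip(target_lat, src.lats[0], src.lats[-1])
    tx = np.clip(target_lon, src.lons[0], src.lons[-1])
    iy = np.clip(np.searchsorted(src.lats, ty, side="right") - 1, 0, src.lats.size - 2)
    ix = np.clip(np.searchsorted(src.lons, tx, side="right") - 1, 0, src.lons.size - 2)
    wy = (ty - src.lats[iy]) / (src.lats[iy + 1] - src.lats[iy])
    wx = (tx - src.lons[ix]) / (src.lons[ix + 1] - src.lons[ix])
    wy = wy[:, None]
    wx = wx[None, :]
    IY, IX = iy[:, None], ix[None, :]

    def _interp(slab: np.ndarray) -> np.ndarray:
        return ((1 - wy) * (1 - wx) * slab[IY, IX]
                + (1 - wy) * wx * slab[IY, IX + 1]
                + wy * (1 - wx) * slab[IY + 1, IX]
                + wy * wx * slab[IY + 1, IX + 1])

    nt = src.axis.n_steps
    out = np.empty((nt, target_lat.size, target_lon.size))
    out_mask = np.empty_like(out, dtype=bool)
    for t in range(nt):
        out[t] = _interp(np.where(src.mask[t], 0.0, src.values[t]))
        stencil_bad = (src.mask[t][IY, IX] | src.mask[t][IY, IX + 1]
                       | src.mask[t][IY + 1, IX] | src.mask[t][IY + 1, IX + 1])
        out_mask[t] = stencil_bad
    out[out_mask] = np.nan
    return GridField(src.name, src.units, target_lat, target_lon, src.axis, out, out_mask)


def extract_box_mean(field: GridField, lat_bounds, lon_bounds) -> np.ndarray:
    """Unweighted mean over unmasked pixels inside a closed lat/lon box.

    Returns a masked series (NaN where no valid pixel) of length n_steps.
    """
    (lat0, lat1), (lon0, lon1) = sorted(lat_bounds), sorted(lon_bounds)
    sel_lat = (field.lats >= lat0) & (field.lats <= lat1)
    sel_lon = (field.lons >= lon0) & (field.lons <= lon1)
    if not (np.any(sel_lat) and np.any(sel_lon)):
        raise ValueError("box contains no grid pixels")
    sub = field.data[:, sel_lat][:, :, sel_lon]
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub.reshape(field.axis.n_steps, -1), axis=1)


# ---------------------------------------------------------------------------
# I/O

def write_bundle(bundle: ForcingBundle, path: str | Path) -> Path:
    """Write a bundle to CF-style NetCDF (dimensions time/lat/lon)."""
    path = Path(path)
    ds = xr.Dataset({name: f.to_dataarray() for name, f in bundle.fields().items()})
    ds["time_window_days"] = xr.DataArray(
        bundle.axis.lengths, dims=("time",),
        attrs={"units": "days", "long_name": "compositing window length"})
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine=_NC_ENGINE)
    ds.close()
    return path


def _field_from_dataset(ds: xr.Dataset, name: str, axis: TimeAxis) -> GridField:
    da = ds[name]
    values = np.asarray(da.values, dtype=float)
    return GridField(name, str(da.attrs.get("units", "")) or "1",
                     np.asarray(ds["lat"].values, dtype=float),
                     np.asarray(ds["lon"].values, dtype=float),
                     axis, values, ~np.isfinite(values))


def read_bundle(path: str | Path, variables=("schl", "nhf", "ws")) -> ForcingBundle:
    """Read a bundle written by :func:`write_bundle`; errors name the
    first missing variable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bundle file not found: {path}")
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        ds = ds.load()
    for var in variables:
        if var not in ds:
            raise KeyError(f"variable {var!r} missing from {path}")
    centers = np.asarray(ds["time"].values, dtype="datetime64[s]")
    if "time_window_days" in ds:
        lengths = np.asarray(ds["time_window_days"].values, dtype=float)
        half = (lengths * 43200).astype("timedelta64[s]")
        axis = TimeAxis(centers - half, lengths)
    else:
        axis = TimeAxis.from_centers(centers)
    fields = {var: _field_from_dataset(ds, var, axis) for var in variables}
    return ForcingBundle(fields["schl"], fields["nhf"], fields["ws"])


def write_pixel_csv(path: str | Path, axis: TimeAxis, schl, nhf, ws) -> Path:
    """Single-pixel series as CSV with columns date, schl, nhf, ws
    (ISO-8601 window-center dates)."""
    path = Path(path)
    df = pd.DataFrame({
        "date": pd.DatetimeIndex(axis.centers).strftime("%Y-%m-%dT%H:%M:%S"),
        "schl": np.asarray(schl, dtype=float),
        "nhf": np.asarray(nhf, dtype=float),
        "ws": np.asarray(ws, dtype=float),
    })
    df.to_csv(path, index=False)
    return path


def read_pixel_csv(path: str | Path) -> tuple[TimeAxis, pd.DataFrame]:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("date", "schl", "nhf", "ws"):
        if col not in df.columns:
            raise KeyError(f"column {col!r} missing from {path}")
    centers = pd.to_datetime(df["date"]).to_numpy().astype("datetime64[s]")
    return TimeAxis.from_centers(centers), df[["schl", "nhf", "ws"]].astype(float)
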