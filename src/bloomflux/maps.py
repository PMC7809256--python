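"""Pixel-wise climatologies, the bloom-region mask, and sign-agreement maps.

The bloom region is defined as the pixels whose climatological spring
(March-April) surface chlorophyll exceeds 0.65 mg Chl m-3.  The
sign-agreement map gives, per pixel and season, the percentage of 8-day
intervals on which the forcing derivative and the SChl net growth rate
have the same sign (for the wind-stress driver, "agreement" means opposite
signs: a drop in wind goes with growth).  Zero-valued derivatives or
growth rates are sign-ambiguous and excluded from both numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid_io import GridField
from .metrics import season_mask
from .timeaxis import TimeAxis

__all__ = [
    "BloomMask",
    "seasonal_climatology",
    "bloom_mask",
    "sign_agreement_map",
    "sign_agreement_series",
    "write_mask_ascii",
    "BLOOM_THRESHOLD",
    "MIN_AGREEMENT_INTERVALS",
]

BLOOM_THRESHOLD = 0.65        # mg Chl m-3, climatological spring SChl
MIN_AGREEMENT_INTERVALS = 5   # pixel-seasons with fewer valid intervals are masked


@dataclass
class BloomMask:
    """Boolean bloom-region mask on a single time slice."""

    values: np.ndarray        # (nlat, nlon) bool
    threshold: float
    lats: np.ndarray
    lons: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


def seasonal_climatology(field: GridField, season: str) -> GridField:
    """Per-pixel mean over all steps of the season, across all years."""
    mask = season_mask(field.axis, season)
    sel = mask.values
    if not np.any(sel):
        raise ValueError(f"axis contains no {season} steps")
    data = field.data[sel]
    with np.errstate(invalid="ignore"):
        clim = np.nanmean(data, axis=0)
    axis1 = field.axis.slice_steps(slice(0, 1))
    values = clim[None]
    return GridField(f"{field.name}_{season}_clim", field.units, field.lats,
                     field.lons, axis1, values, ~np.isfinite(values))


def bloom_mask(spring_clim: GridField, threshold: float = BLOOM_THRESHOLD) -> BloomMask:
    """Strict threshold on the spring climatology; masked pixels are False."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    clim = spring_clim.data[0]
    values = np.where(np.isfinite(clim), clim > threshold, False)
    return BloomMask(values.astype(bool), threshold, spring_clim.lats, spring_clim.lons)


def sign_agreement_series(growth: np.ndarray, driver: np.ndarray,
                          in_season: np.ndarray, driver_kind: str = "nhf",
                          min_intervals: int = MIN_AGREEMENT_INTERVALS) -> float:
    """Percentage of in-season intervals with matching signs (one pixel).

    ``driver_kind='ws'`` counts opposite signs as agreement.  Intervals
    where either series is zero or missing are excluded; NaN if fewer than
    ``min_intervals`` remain.
    """
    if driver_kind not in ("nhf", "ws"):
        raise ValueError(f"unknown driver kind {driver_kind!r}")
    g = np.asarray(growth, dtype=float)[in_season]
    d = np.asarray(driver, dtype=float)[in_season]
    ok = np.isfinite(g) & np.isfinite(d) & (g != 0) & (d != 0)
    n = int(ok.sum())
    if n < min_intervals:
        return float("nan")
    same = np.sign(g[ok]) == np.sign(d[ok])
    agree = ~same if driver_kind == "ws" else same
    return 100.0 * float(agree.sum()) / n


def sign_agreement_map(growth: np.ndarray, driver: np.ndarray, axis: TimeAxis,
                       season: str, lats, lons, driver_kind: str = "nhf",
                       min_intervals: int = MIN_AGREEMENT_INTERVALS) -> GridField:
    """Per-pixel sign-agreement percentage for one season.

    ``growth`` and ``driver`` are interval arrays of shape
    (n-1, nlat, nlon); an interval belongs to the season of its first step.
    """
    sel = season_mask(axis, season).values[:-1]
    nlat, nlon = len(lats), len(lons)
    g = np.asarray(growth, dtype=float).reshape(axis.n_steps - 1, nlat * nlon)
    d = np.asarray(driver, dtype=float).reshape(axis.n_steps - 1, nlat * nlon)
    out = np.empty(nlat * nlon)
    for k in range(nlat * nlon):
        out[k] = sign_agreement_series(g[:, k], d[:, k], sel, driver_kind,
                                       min_intervals)
    values = out.reshape(1, nlat, nlon)
    axis1 = axis.slice_steps(slice(0, 1))
    return GridField(f"sign_agreement_{driver_kind}_{season}", "percent",
                     np.asarray(lats, float), np.asarray(lons, float),
                     axis1, values, ~np.isfinite(values))


def write_mask_ascii(mask: BloomMask, path: str | Path) -> Path:
    """Bloom mask as an ASCII 0/1 grid with a lat/lon header."""
    path = Path(path)
    lines = [
        f"# bloom mask, threshold {mask.threshold} mg Chl m-3",
        "# lat: " + " ".join(f"{v:.4f}" for v in mask.lats),
        "# lon: " + " ".join(f"{v:.4f}" for v in mask.lons),
    ]
    for row in mask.values.astype(int):
        lines.append(" ".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
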