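"""Census X-11-style trend / seasonal / irregular decomposition.

An additive, two-pass moving-average scheme for 8-day series with period
``p = 46`` steps per year:

1. initial trend: centered 2xp moving average (p+1 points, end weights
   1/(2p), interior 1/p);
2. detrended series Z = X - T1;
3. seasonal: for each of the p phases, smooth Z across years with the 3x3
   composite filter (weights 1/9, 2/9, 3/9, 2/9, 1/9), then center the
   result by subtracting its own 2xp moving average;
4. refined trend: 23-term Henderson filter applied to X - S;
5. the seasonal and trend steps are repeated once from the refined trend,
   the second seasonal pass using the smoother 3x5 composite filter
   (weights 1/15, 2/15, 3/15, 3/15, 3/15, 2/15, 1/15), as in the classical
   Census X-11 sequence; the irregular is the exact residual I = X - T - S.

At series ends every kernel is truncated to the available points and
renormalised, so the whole decomposition is linear and reconstruction is
exact everywhere.  The irregular component therefore carries the
sub-seasonal (roughly sub-six-month), non-seasonal variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .grid_io import GridField
from .metrics import season_mask
from .timeaxis import TimeAxis

__all__ = [
    "X11Decomposition",
    "centered_moving_average",
    "henderson_weights",
    "x11_decompose",
    "isv_std_map",
    "isv_normalized_std",
]


@dataclass
class X11Decomposition:
    """Additive components aligned to the input series: X = T + S + I."""

    trend: np.ndarray
    seasonal: np.ndarray
    irregular: np.ndarray
    period: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.trend + self.seasonal + self.irregular


def _masked_filter(values: np.ndarray, valid: np.ndarray, weights: np.ndarray,
                   axis: int = 0) -> np.ndarray:
    """Symmetric filter with truncated-renormalised kernels at the ends and
    around masked points (mask-aware weighted mean)."""
    num = convolve1d(np.where(valid, values, 0.0), weights, axis=axis,
                     mode="constant", cval=0.0)
    den = convolve1d(valid.astype(float), weights, axis=axis,
                     mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def centered_moving_average(series, weights, valid=None) -> np.ndarray:
    """Convolve with a symmetric, odd-length weight vector summing to 1.

    Works on 1-D series or (time, pixel) arrays along axis 0; NaNs and an
    optional ``valid`` mask are handled by kernel renormalisation.
    """
    series = np.asarray(series, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or weights.size % 2 == 0:
        raise ValueError("weights must be a 1-D, odd-length vector")
    total = weights.sum()
    if not np.isfinite(total) or abs(total) < 1e-12:
        raise ValueError("weights must sum to a nonzero value")
    if not np.allclose(total, 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    if not np.allclose(weights, weights[::-1]):
        raise ValueError("weights must be symmetric")
    if valid is None:
        valid = np.isfinite(series)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(series)
    return _masked_filter(series, valid, weights, axis=0)


def _ma_2xp_weights(p: int) -> np.ndarray:
    w = np.full(p + 1, 1.0 / p)
    w[0] = w[-1] = 1.0 / (2.0 * p)
    return w


def henderson_weights(length: int = 23) -> np.ndarray:
    """Henderson filter weights of odd ``length`` (classical closed form)."""
    if length % 2 == 0 or length < 5:
        raise ValueError("Henderson filter length must be odd and >= 5")
    k = (length - 3) // 2
    m = k + 2
    j = np.arange(-(k + 1), k + 2)
    num = (315.0 * ((k + 1) ** 2 - j ** 2) * ((k + 2) ** 2 - j ** 2)
           * ((k + 3) ** 2 - j ** 2) * (3 * (k + 2) ** 2 - 11 * j ** 2 - 16))
    den = (8.0 * m * (m ** 2 - 1) * (4 * m ** 2 - 1)
           * (4 * m ** 2 - 9) * (4 * m ** 2 - 25))
    return num / den


SEASONAL_3X3 = np.array([1, 2, 3, 2, 1], dtype=float) / 9.0
SEASONAL_3X5 = np.array([1, 2, 3, 3, 3, 2, 1], dtype=float) / 15.0


def _seasonal_component(z: np.ndarray, valid: np.ndarray, p: int,
                        weights: np.ndarray = SEASONAL_3X3) -> np.ndarray:
    """Per-phase composite smoothing across years, then centering by a 2xp MA."""
    n = z.shape[0]
    n_years = n // p
    rest = z.shape[1:]
    zy = z[: n_years * p].reshape(n_years, p, *rest)
    vy = valid[: n_years * p].reshape(n_years, p, *rest)
    smoothed = _masked_filter(zy, vy, weights, axis=0).reshape(n_years * p, *rest)
    if n > n_years * p:  # partial final year repeats the last full-year phase values
        tail = n - n_years * p
        smoothed = np.concatenate([smoothed, smoothed[-p:][:tail]], axis=0)
    s_valid = np.isfinite(smoothed)
    center = _masked_filter(np.where(s_valid, smoothed, 0.0), s_valid,
                            _ma_2xp_weights(p), axis=0)
    return smoothed - center


def x11_decompose(series, p: int = 46, valid=None) -> X11Decomposition:
    """Decompose an 8-day series (1-D, or (time, pixel)) into trend,
    seasonal and irregular components with exact additive reconstruction."""
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3 * p:
        raise ValueError(f"series must cover at least 3 full years ({3 * p} steps)")
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    xf = np.where(valid, x, 0.0)

    w2p = _ma_2xp_weights(p)
    hend = henderson_weights(23)

    t1 = _masked_filter(xf, valid, w2p)
    s1 = _seasonal_component(np.where(valid, x - t1, np.nan), valid, p, SEASONAL_3X3)
    d1 = np.where(valid, x - s1, np.nan)
    t2 = _masked_filter(np.where(valid, d1, 0.0), valid & np.isfinite(d1), hend)

    s = _seasonal_component(np.where(valid, x - t2, np.nan), valid, p, SEASONAL_3X5)
    d2 = np.where(valid, x - s, np.nan)
    trend = _masked_filter(np.where(valid, d2, 0.0), valid & np.isfinite(d2), hend)

    irregular = np.where(valid, x - trend - s, np.nan)
    trend = np.where(valid, trend, np.nan)
    seasonal = np.where(valid, s, np.nan)
    return X11Decomposition(trend=trend, seasonal=seasonal, irregular=irregular, period=p)


def isv_normalized_std(irregular: np.ndarray, schl: np.ndarray,
                       in_season: np.ndarray) -> np.ndarray:
    """STD of the irregular component over the season's steps, divided by the
    seasonal-mean SChl (population STD; NaN where the mean is <= 0)."""
    irr = irregular[in_season]
    chl = schl[in_season]
    with np.errstate(invalid="ignore"):
        std = np.nanstd(irr, axis=0)
        mean = np.nanmean(chl, axis=0)
    out = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.nan)
    counts = np.sum(np.isfinite(irr), axis=0)
    out = np.where(counts >= 2, out, np.nan)
    return out


def isv_std_map(schl: GridField, season: str, p: int = 46) -> GridField:
    """Map of normalized intraseasonal SChl variability for one season.

    Per pixel: STD of the X-11 irregular component over the season's steps
    across all years, normalized by that pixel's seasonal-mean SChl.
    """
    mask = season_mask(schl.axis, season)  # raises on unknown season
    flat = schl.data.reshape(schl.axis.n_steps, -1)
    dec = x11_decompose(flat, p=p)
    ratio = isv_normalized_std(dec.irregular, flat, mask.values)
    values = ratio.reshape(1, schl.lats.size, schl.lons.size)
    axis1 = schl.axis.slice_steps(slice(0, 1))
    return GridField(f"schl_isv_std_{season}", "1", schl.lats, schl.lons,
                     axis1, values, ~np.isfinite(values))
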