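"""Per-pixel scalar metrics: flux assembly, wind stress, net growth rate,
one-step derivatives and season masks.

All time derivatives — net growth, d(NHF)/dt, d(WS)/dt — are computed
between two consecutive 8-day steps and reported per day.  The net growth
rate is the log-scale derivative d ln(SChl)/dt, so it is invariant to any
constant calibration factor in the chlorophyll product.  A derivative
interval is assigned to the season of its first step: the forcing change
precedes the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeaxis import TimeAxis

__all__ = [
    "DerivedSeries",
    "SeasonMask",
    "net_heat_flux",
    "wind_stress",
    "net_growth_rate",
    "forward_derivative",
    "season_mask",
    "derive_series",
]

STEP_DAYS = 8.0
RHO_AIR = 1.22        # kg m-3
DRAG_COEFF = 1.3e-3   # bulk drag coefficient

SEASON_MONTHS = {"winter": (1, 2), "spring": (3, 4)}


@dataclass(frozen=True)
class SeasonMask:
    """Boolean per-step mask; a step belongs to the month of its window
    center (winter = Jan-Feb, spring = Mar-Apr)."""

    label: str
    values: np.ndarray


@dataclass
class DerivedSeries:
    """Interval quantities (length n-1) on the intervals between steps."""

    axis: TimeAxis             # the parent step axis (length n)
    growth: np.ndarray         # day-1
    dnhf: np.ndarray           # W m-2 day-1
    dws: np.ndarray            # N m-2 day-1

    @property
    def n_intervals(self) -> int:
        return self.axis.n_steps - 1

    def interval_season(self, label: str) -> np.ndarray:
        """Interval mask: the season of the interval's first step."""
        return season_mask(self.axis, label).values[:-1]

    def interval_in_months(self, months) -> np.ndarray:
        return np.isin(self.axis.months, list(months))[:-1]


def _masked(series) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    return arr


def net_heat_flux(sw, lw, latent, sensible) -> np.ndarray:
    """NHF as the sum of shortwave, longwave, latent and sensible fluxes
    (positive = ocean heat gain); NaN propagates from any missing term."""
    parts = [_masked(p) for p in (sw, lw, latent, sensible)]
    shape = parts[0].shape
    for p in parts[1:]:
        if p.shape != shape:
            raise ValueError("flux components must have equal lengths")
    return parts[0] + parts[1] + parts[2] + parts[3]


def wind_stress(u10, v10, rho_air: float = RHO_AIR, c_d: float = DRAG_COEFF) -> np.ndarray:
    """Bulk wind stress tau = rho_air * c_d * (u^2 + v^2) from 10 m wind
    components in m s-1."""
    if rho_air <= 0 or c_d <= 0:
        raise ValueError("rho_air and c_d must be positive")
    u = _masked(u10)
    v = _masked(v10)
    return rho_air * c_d * (u * u + v * v)


def net_growth_rate(schl, step_days: float = STEP_DAYS) -> np.ndarray:
    """r_t = (ln S_{t+1} - ln S_t) / dt on consecutive-step intervals."""
    s = _masked(schl)
    if s.shape[0] < 2:
        raise ValueError("need at least two steps to form a growth rate")
    finite = np.isfinite(s)
    bad = finite & (s <= 0)
    if np.any(bad):
        idx = int(np.argwhere(bad)[0][0])
        raise ValueError(f"non-positive SChl at unmasked step {idx}")
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(finite, np.log(np.where(finite & (s > 0), s, 1.0)), np.nan)
    return (logs[1:] - logs[:-1]) / step_days


def forward_derivative(series, step_days: float = STEP_DAYS) -> np.ndarray:
    """(x_{t+1} - x_t) / dt per consecutive-step interval."""
    x = _masked(series)
    if x.shape[0] < 2:
        raise ValueError("need at least two steps to form a derivative")
    return (x[1:] - x[:-1]) / step_days


def season_mask(axis: TimeAxis, label: str) -> SeasonMask:
    """Per-step winter (Jan-Feb) or spring (Mar-Apr) membership."""
    if label not in SEASON_MONTHS:
        raise ValueError(f"unknown season {label!r}; expected one of {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[label]
    return SeasonMask(label, np.isin(axis.months, months))


def derive_series(schl, nhf, ws, axis: TimeAxis) -> DerivedSeries:
    """Bundle growth, dNHF/dt and dWS/dt on common intervals."""
    return DerivedSeries(
        axis=axis,
        growth=net_growth_rate(schl),
        dnhf=forward_derivative(nhf),
        dws=forward_derivative(ws),
    )
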