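"""NHF-sign phases, zero-crossing events, lag composites and binned
growth-stability relations.

The convection-shutdown analysis distinguishes, for each pair of
consecutive 8-day steps inside the January-April window, four situations
from the sign of the net heat flux (zero counts as stable/positive, since
shutdown means buoyancy loss has ceased):

* ``WINTER_UNSTABLE``      (-,-)  active convective mixing persists,
* ``TRANSITION_SHUTDOWN``  (-,+)  convection shuts down,
* ``TRANSITION_RESUME``    (+,-)  convection resumes,
* ``SPRING_STABLE``        (+,+)  the stratified situation persists.

The lag composite aligns the net growth rate on the *last persistent*
negative-to-positive crossing of each pixel-year (t = 0); the lag-0 growth
interval spans the crossing itself, i.e. it ends at the first step with
NHF >= 0.  The binned relation uses *all* crossings (and the other
phases), bin-averaging growth against the forcing derivative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .metrics import DerivedSeries
from .timeaxis import TimeAxis

__all__ = [
    "PhaseLabel",
    "ZeroCrossingEvent",
    "CompositeResult",
    "BinnedRelation",
    "classify_pair",
    "classify_intervals",
    "find_zero_crossings",
    "last_persistent_crossing",
    "composite_about_crossing",
    "aggregate_composite",
    "bin_relation",
    "analysis_window_mask",
    "DEFAULT_LAGS",
]

STEP_DAYS = 8.0
DEFAULT_LAGS = (-3, -2, -1, 0, 1, 2, 3)  # in steps; x8 for days
WINDOW_MONTHS = (1, 2, 3, 4)  # the Jan 1 - Apr 30 analysis window


class PhaseLabel(enum.Enum):
    WINTER_UNSTABLE = "winter_unstable"
    TRANSITION_SHUTDOWN = "transition_shutdown"
    TRANSITION_RESUME = "transition_resume"
    SPRING_STABLE = "spring_stable"


PHASE_GROUPS = {
    "winter": (PhaseLabel.WINTER_UNSTABLE,),
    "transition": (PhaseLabel.TRANSITION_SHUTDOWN, PhaseLabel.TRANSITION_RESUME),
    "shutdown": (PhaseLabel.TRANSITION_SHUTDOWN,),
    "resume": (PhaseLabel.TRANSITION_RESUME,),
    "spring": (PhaseLabel.SPRING_STABLE,),
}


@dataclass(frozen=True)
class ZeroCrossingEvent:
    """A sign change of NHF inside one pixel-year analysis window.

    ``index`` is the global step index of the first step on the new sign
    (for neg->pos: NHF_{index-1} < 0 <= NHF_{index}).
    """

    index: int
    year: int
    direction: str            # "neg_pos" | "pos_neg"
    persistent: bool          # neg->pos and NHF >= 0 through the window end
    pixel: int | None = None


@dataclass
class CompositeResult:
    """Aggregated lag composite: per lag, mean growth, STD and count."""

    lags_days: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    count: np.ndarray
    n_events: int


@dataclass
class BinnedRelation:
    """Bin-averaged growth against a forcing-derivative driver."""

    driver: str
    edges: np.ndarray
    centers: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    count: np.ndarray
    reliable: np.ndarray      # count >= min_count
    phase: str


def classify_pair(nhf_t: float, nhf_t1: float) -> PhaseLabel:
    """Phase of one consecutive-step pair from the NHF signs (>= 0 is
    'positive': buoyancy loss has ceased)."""
    if not (np.isfinite(nhf_t) and np.isfinite(nhf_t1)):
        raise ValueError("classify_pair requires finite NHF values")
    neg0, neg1 = nhf_t < 0.0, nhf_t1 < 0.0
    if neg0 and neg1:
        return PhaseLabel.WINTER_UNSTABLE
    if neg0 and not neg1:
        return PhaseLabel.TRANSITION_SHUTDOWN
    if not neg0 and neg1:
        return PhaseLabel.TRANSITION_RESUME
    return PhaseLabel.SPRING_STABLE


def classify_intervals(nhf: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_pair` over all n-1 intervals."""
    nhf = np.asarray(nhf, dtype=float)
    neg0 = nhf[:-1] < 0
    neg1 = nhf[1:] < 0
    out = np.empty(nhf.size - 1, dtype=object)
    out[neg0 & neg1] = PhaseLabel.WINTER_UNSTABLE
    out[neg0 & ~neg1] = PhaseLabel.TRANSITION_SHUTDOWN
    out[~neg0 & neg1] = PhaseLabel.TRANSITION_RESUME
    out[~neg0 & ~neg1] = PhaseLabel.SPRING_STABLE
    finite = np.isfinite(nhf[:-1]) & np.isfinite(nhf[1:])
    out[~finite] = None
    return out


def analysis_window_mask(axis: TimeAxis) -> np.ndarray:
    """Steps whose window center falls in January-April."""
    return np.isin(axis.months, WINDOW_MONTHS)


def find_zero_crossings(nhf: np.ndarray, axis: TimeAxis,
                        pixel: int | None = None) -> list[ZeroCrossingEvent]:
    """All NHF sign changes inside each year's Jan-Apr window, in time
    order, with persistence judged within the window only."""
    nhf = np.asarray(nhf, dtype=float)
    if nhf.shape != (axis.n_steps,):
        raise ValueError("nhf series must match the time axis")
    in_window = analysis_window_mask(axis)
    if not np.any(in_window):
        raise ValueError("time axis contains no steps in the Jan-Apr window")
    years = axis.years
    events: list[ZeroCrossingEvent] = []
    for year in np.unique(years[in_window]):
        idx = np.nonzero(in_window & (years == year))[0]
        vals = nhf[idx]
        ok = np.isfinite(vals)
        neg = vals < 0
        for k in range(1, idx.size):
            if not (ok[k - 1] and ok[k]) or neg[k - 1] == neg[k]:
                continue
            if neg[k - 1] and not neg[k]:
                later = vals[k:][ok[k:]]
                persistent = bool(np.all(later >= 0))
                events.append(ZeroCrossingEvent(int(idx[k]), int(year),
                                                "neg_pos", persistent, pixel))
            else:
                events.append(ZeroCrossingEvent(int(idx[k]), int(year),
                                                "pos_neg", False, pixel))
    return events


def last_persistent_crossing(events: list[ZeroCrossingEvent]) -> ZeroCrossingEvent | None:
    """The unique persistent neg->pos event of one pixel-year, or None."""
    persistent = [e for e in events if e.direction == "neg_pos" and e.persistent]
    if not persistent:
        return None
    return max(persistent, key=lambda e: e.index)


def composite_about_crossing(growth: np.ndarray, event: ZeroCrossingEvent,
                             axis: TimeAxis, lags=DEFAULT_LAGS) -> np.ndarray:
    """Growth at each lag around one persistent crossing (NaN outside the
    data or outside the event's Jan-Apr window).

    Lag ``l`` (in steps) reads the growth interval ``[c-1+l, c+l]``; lag 0
    spans the crossing itself.
    """
    if event.direction != "neg_pos" or not event.persistent:
        raise ValueError("composite requires a persistent neg->pos crossing")
    growth = np.asarray(growth, dtype=float)
    in_window = analysis_window_mask(axis) & (axis.years == event.year)
    out = np.full(len(lags), np.nan)
    for j, lag in enumerate(lags):
        i = event.index - 1 + lag
        if 0 <= i < growth.size and in_window[i] and in_window[i + 1]:
            out[j] = growth[i]
    return out


def aggregate_composite(contributions: list[np.ndarray],
                        lags=DEFAULT_LAGS) -> CompositeResult:
    """Mean / STD / count per lag over all pixel-year events."""
    lags_days = np.asarray(lags, dtype=float) * STEP_DAYS
    if not contributions:
        n = len(lags)
        return CompositeResult(lags_days, np.full(n, np.nan),
                               np.full(n, np.nan), np.zeros(n, dtype=int), 0)
    arr = np.vstack(contributions)
    count = np.sum(np.isfinite(arr), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count >= 1, np.nanmean(arr, axis=0), np.nan)
        std = np.where(count >= 1, np.nanstd(arr, axis=0), np.nan)
    return CompositeResult(lags_days, mean, std, count.astype(int), arr.shape[0])


def _default_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = np.nanpercentile(values, [1.0, 99.0])
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        lo, hi = np.nanmin(values), np.nanmax(values)
        if hi <= lo:
            hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def bin_relation(derived: DerivedSeries, phase: str, driver: str = "dnhf",
                 edges=None, n_bins: int = 9, min_count: int = 10,
                 interval_mask: np.ndarray | None = None,
                 nhf: np.ndarray | None = None,
                 phase_labels: np.ndarray | None = None) -> BinnedRelation:
    """Bin-average growth against a forcing derivative for one phase group.

    ``phase`` is one of winter / transition / shutdown / resume / spring
    (or "all").  Intervals outside the Jan-Apr window are excluded; pass
    ``interval_mask`` to restrict further.  Default bins: ``n_bins``
    equal-width bins over the central 98% of the driver values.
    """
    if driver not in ("dnhf", "dws"):
        raise ValueError(f"unknown driver {driver!r}")
    if phase != "all" and phase not in PHASE_GROUPS:
        raise ValueError(f"unknown phase {phase!r}")
    growth = derived.growth
    drv = derived.dnhf if driver == "dnhf" else derived.dws

    if phase_labels is None:
        if nhf is None:
            raise ValueError("bin_relation needs the nhf series (or phase_labels)")
        phase_labels = classify_intervals(nhf)
    sel = np.ones(derived.n_intervals, dtype=bool)
    if phase != "all":
        wanted = set(PHASE_GROUPS[phase])
        sel &= np.array([lab in wanted for lab in phase_labels])
    window = analysis_window_mask(derived.axis)
    sel &= window[:-1] & window[1:]
    if interval_mask is not None:
        sel &= np.asarray(interval_mask, dtype=bool)
    sel &= np.isfinite(growth) & np.isfinite(drv)

    g, d = growth[sel], drv[sel]
    if edges is None:
        if g.size == 0:
            raise ValueError(f"no intervals match phase {phase!r}")
        edges = _default_edges(d, n_bins)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    nb = edges.size - 1
    which = np.digitize(d, edges) - 1
    inside = (which >= 0) & (which < nb)
    mean = np.full(nb, np.nan)
    std = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        vals = g[inside & (which == b)]
        count[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            std[b] = vals.std()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedRelation(driver, edges, centers, mean, std, count,
                          count >= min_count, phase)
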