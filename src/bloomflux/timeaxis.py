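"""Calendar handling for 8-day composite time series.

Ocean-colour composites are anchored to January 1 of each year: windows
0..44 span 8 days each and the 46th window runs from day 361 to the end of
the year (5 days, 6 in leap years).  Every step carries its window start
date and window length; the window *center* date is what determines the
step's month, season and day-of-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeAxis"]


@dataclass(frozen=True)
class TimeAxis:
    """Time axis of consecutive compositing windows.

    Parameters
    ----------
    starts
        Window start dates, ``datetime64[s]``, strictly increasing.
    lengths
        Window length in days (float, typically 8; the final window of a
        Jan-1-anchored year may be shorter).
    """

    starts: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype="datetime64[s]")
        lengths = np.asarray(self.lengths, dtype=float)
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("TimeAxis requires a non-empty 1-D array of start dates")
        if lengths.shape != starts.shape:
            raise ValueError("starts and lengths must have matching shapes")
        if np.any(np.diff(starts).astype("timedelta64[s]").astype(float) <= 0):
            raise ValueError("window start dates must be strictly increasing")
        if np.any(lengths <= 0):
            raise ValueError("window lengths must be positive")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "lengths", lengths)

    # -- constructors ---------------------------------------------------

    @classmethod
    def eight_day(cls, start_year: int, n_years: int, steps_per_year: int = 46) -> "TimeAxis":
        """Jan-1-anchored composite windows covering ``n_years`` full years."""
        if n_years <= 0:
            raise ValueError("n_years must be positive")
        if not 1 <= steps_per_year or steps_per_year * 8 > 368:
            raise ValueError("steps_per_year * 8 must not exceed 368")
        starts, lengths = [], []
        for year in range(start_year, start_year + n_years):
            jan1 = np.datetime64(f"{year:04d}-01-01", "s")
            days_in_year = (np.datetime64(f"{year + 1:04d}-01-01", "D")
                            - np.datetime64(f"{year:04d}-01-01", "D")).astype(int)
            for i in range(steps_per_year):
                start_day = 8 * i
                length = min(8, days_in_year - start_day)
                if length <= 0:
                    raise ValueError("steps_per_year too large for calendar year")
                starts.append(jan1 + np.timedelta64(start_day * 86400, "s"))
                lengths.append(float(length))
        return cls(np.array(starts, dtype="datetime64[s]"), np.array(lengths))

    @classmethod
    def uniform(cls, start: str | np.datetime64, n_steps: int, step_days: float = 8.0) -> "TimeAxis":
        if n_steps <= 0:
            raise ValueError("n_steps must be positive")
        s0 = np.datetime64(start, "s")
        step = np.timedelta64(int(round(step_days * 86400)), "s")
        starts = s0 + step * np.arange(n_steps)
        return cls(starts, np.full(n_steps, float(step_days)))

    @classmethod
    def from_centers(cls, centers, step_days: float = 8.0) -> "TimeAxis":
        centers = np.asarray(centers, dtype="datetime64[s]")
        half = np.timedelta64(int(round(step_days * 43200)), "s")
        return cls(centers - half, np.full(centers.shape, float(step_days)))

    # -- derived quantities ---------------------------------------------

    @property
    def n_steps(self) -> int:
        return int(self.starts.size)

    @property
    def centers(self) -> np.ndarray:
        """Window-center dates, ``datetime64[s]``."""
        half = (self.lengths * 43200).astype("timedelta64[s]")
        return self.starts + half

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.centers)

    @property
    def months(self) -> np.ndarray:
        return self.index.month.to_numpy()

    @property
    def years(self) -> np.ndarray:
        return self.index.year.to_numpy()

    @property
    def doy(self) -> np.ndarray:
        """Day-of-year of the window center (float, includes half days)."""
        idx = self.index
        frac = (idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0) / 24.0
        return idx.dayofyear.to_numpy() + frac

    def __len__(self) -> int:
        return self.n_steps

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeAxis):
            return NotImplemented
        return (self.starts.shape == other.starts.shape
                and bool(np.all(self.starts == other.starts))
                and bool(np.allclose(self.lengths, other.lengths)))

    def slice_steps(self, indices) -> "TimeAxis":
        return TimeAxis(self.starts[indices], self.lengths[indices])
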