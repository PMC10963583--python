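"""Hour-of-day × week-of-year (or day-of-year) time grouping.

Bias corrections operate within groups that preserve both the diurnal
and the annual cycle: every hourly timestamp is assigned an
(hour, block) key, where the block is the ISO week of year (weekly mode,
weeks 53 merged into 52) or the day of year (daily mode, with Feb 29
merged into Feb 28 so calendar dates align across leap and common
years — equivalently, day 366 folds into day 365).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import InputError

WEEKLY, DAILY = "weekly", "daily"
N_BLOCKS = {WEEKLY: 52, DAILY: 365}


@dataclass
class TimeGroups:
    """Per-timestamp group assignment and its dense integer encoding."""

    mode: str
    hour: np.ndarray   # 0..23
    block: np.ndarray  # 1..52 (weekly) or 1..365 (daily)

    @property
    def n_groups(self) -> int:
        return 24 * N_BLOCKS[self.mode]

    @property
    def gid(self) -> np.ndarray:
        """Dense group id: hour * n_blocks + (block - 1)."""
        return self.hour * N_BLOCKS[self.mode] + (self.block - 1)


def build_time_groups(timestamps: pd.DatetimeIndex, mode: str = WEEKLY) -> TimeGroups:
    """Assign each hourly timestamp its (hour, block) group key."""
    if mode not in N_BLOCKS:
        raise InputError(f"unknown grouping mode {mode!r}")
    if not isinstance(timestamps, pd.DatetimeIndex):
        timestamps = pd.DatetimeIndex(timestamps)
    dt = np.diff(timestamps.asi8)
    if len(dt) and not np.all(dt == 3_600_000_000_000):
        raise InputError("time grouping requires strictly hourly timestamps")

    hour = timestamps.hour.to_numpy()
    if mode == WEEKLY:
        block = timestamps.isocalendar().week.to_numpy().astype(np.int64)
        block[block == 53] = 52
    else:
        doy = timestamps.dayofyear.to_numpy().astype(np.int64)
        leap = np.asarray(timestamps.is_leap_year)
        # fold Feb 29 (doy 60 in leap years) into Feb 28 and realign the rest
        block = np.where(leap & (doy >= 60), doy - 1, doy)
    return TimeGroups(mode=mode, hour=hour, block=block)
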