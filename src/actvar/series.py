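"""Core in-memory containers for minute-level activity data.

A participant's record is a gap-free 1-minute grid of MET (metabolic
equivalent of task) values together with a per-minute sleep-state label.
Missing observations are explicit ``NaN`` entries in the MET column, never
absent rows, so every downstream stage can reason about missingness
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

AWAKE = "awake"
ASLEEP = "asleep"


@dataclass
class ActivityTimeSeries:
    """One participant's minute-indexed MET series with sleep-state labels.

    Parameters
    ----------
    participant_id:
        Opaque participant identifier.
    data:
        DataFrame indexed by a strictly increasing, gap-free 1-minute
        ``DatetimeIndex`` with columns ``met`` (float, ``NaN`` = missing)
        and ``state`` (``"awake"``/``"asleep"``).
    """

    participant_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            raise ValueError("empty activity series")
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("index must be a DatetimeIndex")
        # cheap grid check: constant 60 s spacing
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not (deltas == 60_000_000_000).all():
                raise ValueError("index must be a gap-free 1-minute grid")
        missing_cols = {"met", "state"} - set(self.data.columns)
        if missing_cols:
            raise ValueError(f"missing columns: {sorted(missing_cols)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def met(self) -> pd.Series:
        return self.data["met"]

    @property
    def state(self) -> pd.Series:
        return self.data["state"]

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data["met"].isna().to_numpy()

    @property
    def missingness_pct(self) -> float:
        """Percentage of minutes with a missing MET value."""
        return 100.0 * float(self.missing_mask.mean())

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def n_days(self) -> int:
        return int(np.ceil(self.n_minutes / MINUTES_PER_DAY))

    def copy(self) -> "ActivityTimeSeries":
        return ActivityTimeSeries(self.participant_id, self.data.copy())

    def state_numeric(self) -> pd.Series:
        """Sleep state as 0/1 (0 = asleep, 1 = awake), NaN where unknown."""
        s = self.data["state"]
        out = pd.Series(np.where(s == AWAKE, 1.0, np.where(s == ASLEEP, 0.0, np.nan)),
                        index=s.index, name="state")
        return out


@dataclass
class SleepSummary:
    """Per-day sleep intervals for one participant.

    ``records`` has columns ``date`` (the day the interval is reported on),
    ``sleep_start`` and ``sleep_end`` (timestamps, end exclusive).
    """

    participant_id: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        need = {"date", "sleep_start", "sleep_end"}
        if not need <= set(self.records.columns):
            raise ValueError(f"sleep summary needs columns {sorted(need)}")
        if len(self.records):
            if not (self.records["sleep_end"] > self.records["sleep_start"]).all():
                raise ValueError("sleep_end must be after sleep_start")


def minute_grid(start: pd.Timestamp, n_days: int) -> pd.DatetimeIndex:
    """The canonical 1-minute grid covering ``n_days`` days from midnight."""
    start = pd.Timestamp(start).normalize()
    return pd.date_range(start, periods=n_days * MINUTES_PER_DAY, freq="min")
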