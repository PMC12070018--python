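"""Ingestion and cleaning of raw minute-level MET data.

Raw files are normalized onto a gap-free 1-minute grid (duplicates dropped,
absent minutes made explicit), sleep state is labeled from a per-day sleep
summary using the longest sleep interval of each day, sub-floor MET values
(< 0.9, non-wear artifacts) are dropped to missing, and participants whose
missingness exceeds a threshold are excluded from the cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import ASLEEP, AWAKE, MINUTES_PER_DAY, ActivityTimeSeries, SleepSummary, minute_grid

log = logging.getLogger(__name__)

MET_FLOOR = 0.9
MISSINGNESS_THRESHOLD_PCT = 29.0


def ingest(path, participant_id: str, *, window_start=None,
           n_days: int | None = None) -> ActivityTimeSeries:
    """Read a minute-level CSV/Parquet file onto the canonical grid.

    Duplicate timestamps keep the first occurrence; minutes absent from the
    file become explicit missing entries.  Rows whose timestamp or MET value
    cannot be parsed are logged and treated as missing.  The grid spans
    ``[window_start, window_start + n_days)``, defaulting to the calendar
    days covered by the file.
    """
    path = Path(path)
    if path.suffix == ".parquet":
        raw = pd.read_parquet(path)
    else:
        raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"{path}: empty input file")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    met = pd.to_numeric(raw["met"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        log.warning("%s: %d unparseable rows treated as missing",
                    participant_id, int(bad.sum()))
    ts = ts[~bad].dt.floor("min")
    met = met[~bad]
    state = raw.get("state")
    state = state[~bad] if state is not None else None

    frame = pd.DataFrame({"met": met.to_numpy()}, index=ts)
    if state is not None:
        frame["state"] = state.to_numpy()
    dup = frame.index.duplicated(keep="first")
    if dup.any():
        log.info("%s: dropped %d duplicate time points", participant_id,
                 int(dup.sum()))
        frame = frame[~dup]
    frame = frame.sort_index()

    if window_start is None:
        window_start = frame.index[0].normalize()
    if n_days is None:
        last = frame.index[-1]
        n_days = int((last.normalize() - pd.Timestamp(window_start).normalize()).days) + 1
    grid = minute_grid(window_start, n_days)
    frame = frame.reindex(grid)
    if "state" not in frame.columns:
        frame["state"] = AWAKE
    else:
        frame["state"] = frame["state"].where(frame["state"].isin([AWAKE, ASLEEP]),
                                              AWAKE)
    return ActivityTimeSeries(participant_id, frame[["met", "state"]])


def read_sleep_summary(path, participant_id: str | None = None):
    """Read a sleep-summary CSV (participant_id, date, sleep_start, sleep_end).

    Returns a single :class:`SleepSummary` when ``participant_id`` is given,
    otherwise a dict keyed by participant id.
    """
    raw = pd.read_csv(path, parse_dates=["date", "sleep_start", "sleep_end"])
    if participant_id is not None:
        sub = raw[raw["participant_id"] == participant_id]
        return SleepSummary(participant_id, sub.reset_index(drop=True))
    return {pid: SleepSummary(pid, g.reset_index(drop=True))
            for pid, g in raw.groupby("participant_id")}


def label_sleep(series: ActivityTimeSeries,
                summary: SleepSummary) -> ActivityTimeSeries:
    """Label minutes asleep using each day's longest sleep interval.

    Intervals may cross midnight; their minutes are attributed to calendar
    days minute-by-minute.  Days with no sleep record stay fully awake.
    When a day carries several records only the longest is used (a warning
    is logged).
    """
    rec = summary.records
    new = series.copy()
    state = np.full(series.n_minutes, AWAKE, dtype=object)
    if len(rec):
        dur = rec["sleep_end"] - rec["sleep_start"]
        per_day = rec.assign(_dur=dur).sort_values("_dur", ascending=False)
        multi = per_day.duplicated(subset="date", keep=False)
        if multi.any():
            log.warning("%s: overlapping sleep records on %d day(s); "
                        "keeping the longest", series.participant_id,
                        per_day.loc[multi, "date"].nunique())
        per_day = per_day.drop_duplicates(subset="date", keep="first")
        idx = series.data.index
        t0, t1 = idx[0], idx[-1]
        for _, row in per_day.iterrows():
            a = max(pd.Timestamp(row["sleep_start"]).floor("min"), t0)
            b = min(pd.Timestamp(row["sleep_end"]).floor("min"), t1 + pd.Timedelta(minutes=1))
            if b <= a:
                continue
            i = idx.searchsorted(a)
            j = idx.searchsorted(b)
            state[i:j] = ASLEEP
    new.data["state"] = pd.Categorical(state, categories=[AWAKE, ASLEEP])
    return new


def apply_met_floor(series: ActivityTimeSeries,
                    floor: float = MET_FLOOR) -> ActivityTimeSeries:
    """Drop MET values below the floor (non-wear artifacts) to missing.

    Values exactly at the floor are retained; the operation is idempotent.
    """
    new = series.copy()
    met = new.data["met"].to_numpy(copy=True)
    met[met < floor] = np.nan
    new.data["met"] = met
    return new


def exclude_by_missingness(cohort: Sequence[ActivityTimeSeries],
                           threshold_pct: float = MISSINGNESS_THRESHOLD_PCT):
    """Split a cohort into (kept, excluded) by participant-level missingness.

    Participants whose percentage of missing MET minutes is *strictly*
    greater than ``threshold_pct`` are excluded.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    kept, excluded = [], []
    for ats in cohort:
        (excluded if ats.missingness_pct > threshold_pct else kept).append(ats)
    log.info("missingness filter (> %.1f%%): kept %d, excluded %d",
             threshold_pct, len(kept), len(excluded))
    return kept, excluded


def preprocess_cohort(series_iter: Iterable[ActivityTimeSeries],
                      summaries: dict[str, SleepSummary] | None = None,
                      *, floor: float = MET_FLOOR,
                      threshold_pct: float = MISSINGNESS_THRESHOLD_PCT):
    """Full preprocessing pass: sleep labeling, MET floor, exclusion."""
    out = []
    for ats in series_iter:
        if summaries is not None and ats.participant_id in summaries:
            ats = label_sleep(ats, summaries[ats.participant_id])
        out.append(apply_met_floor(ats, floor))
    return exclude_by_missingness(out, threshold_pct)
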