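"""Daily MET aggregation by sleep state.

Each participant-day is summarized by three MET-minute sums — over all 1440
minutes, over awake minutes, and over asleep minutes — plus minutes-in-state
counts.  Filling must precede summarization: a residual missing value is an
error, not silently a zero.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import ASLEEP, AWAKE, MINUTES_PER_DAY, ActivityTimeSeries

DRIVER_LABELS = ("baseline_sleep", "sleep_movement", "awake_rest",
                 "awake_movement", "intentional_exercise")


def summarize_days(series: ActivityTimeSeries) -> pd.DataFrame:
    """Per-day 24-h / awake / asleep MET sums and minutes-in-state counts.

    Returns a DataFrame with columns ``participant_id, date, sum_24h,
    sum_awake, sum_asleep, minutes_awake, minutes_asleep``.
    """
    met = series.met.to_numpy()
    if np.isnan(met).any():
        raise ValueError("series contains missing values; fill before summarizing")
    if series.n_minutes % MINUTES_PER_DAY != 0:
        raise ValueError("series must cover whole days")
    days = series.n_minutes // MINUTES_PER_DAY
    awake = (series.state.to_numpy() == AWAKE).reshape(days, MINUTES_PER_DAY)
    met2 = met.reshape(days, MINUTES_PER_DAY)
    sum_awake = np.where(awake, met2, 0.0).sum(axis=1)
    sum_24h = met2.sum(axis=1)
    dates = series.data.index[::MINUTES_PER_DAY].normalize()
    return pd.DataFrame({
        "participant_id": series.participant_id,
        "date": dates,
        "sum_24h": sum_24h,
        "sum_awake": sum_awake,
        "sum_asleep": sum_24h - sum_awake,
        "minutes_awake": awake.sum(axis=1),
        "minutes_asleep": MINUTES_PER_DAY - awake.sum(axis=1),
    })


def summarize_cohort(cohort: Iterable[ActivityTimeSeries]) -> pd.DataFrame:
    """Stacked daily summaries for many participants."""
    return pd.concat([summarize_days(s) for s in cohort], ignore_index=True)


def summarize_participant(days: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of the daily sums per state for one participant."""
    if len(days) < 2:
        raise ValueError("participant summary needs at least 2 days")
    rows = []
    for state, col in (("24h", "sum_24h"), ("awake", "sum_awake"),
                       ("asleep", "sum_asleep")):
        v = days[col].to_numpy()
        rows.append({"state": state, "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1))})
    return pd.DataFrame(rows)


def classify_minute_driver(met: float, state: str) -> str:
    """Driver-of-variability label for one (MET, state) minute.

    Asleep minutes: exactly 0.9 is baseline sleep, above 0.9 is sleep
    movement.  Awake minutes: [1.0, 1.5] is awake movement, > 1.5 is
    intentional exercise, and the sub-rest band [0.9, 1.0) is awake rest.
    """
    if met < 0.9:
        raise ValueError("MET below the 0.9 floor; apply the floor filter first")
    if state == ASLEEP:
        return "baseline_sleep" if met == 0.9 else "sleep_movement"
    if state == AWAKE:
        if met > 1.5:
            return "intentional_exercise"
        if met >= 1.0:
            return "awake_movement"
        return "awake_rest"
    raise ValueError(f"unknown state {state!r}")
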