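"""Gap filling for minute-level activity series.

Four fillers are provided:

``phase_dependent``
    Builds a "median week" per data half — the median value of each
    (day-of-week, minute) cell over one half of the record (103 days for a
    206-day record) — and fills each missing minute from the cell matching
    its phase.  Cells never observed are forward-filled from the preceding
    minute of the grid, wrapping across day-of-week boundaries.
``linear``
    Linear interpolation with a two-way limit direction so leading and
    trailing gaps are also filled (by nearest-observation extension).
``global_median``
    Every gap takes the participant-wide median of observed values.
``zero``
    Gaps become 0 — equivalent to not filling at all when daily sums are
    the downstream statistic, since absent values contribute nothing to a
    sum.

An evaluation harness injects a grid of synthetic gap lengths into observed
data, fills with every method, scores each (method, gap length) by the sum
of absolute differences between predictions and the held-out truth across
all participants, and returns the arg-min policy per gap length.  Test
indices whose true value was itself missing are counted as indeterminate
and excluded from the error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import MINUTES_PER_DAY, ActivityTimeSeries
from .synthetic import inject_missingness

log = logging.getLogger(__name__)

GAP_GRID = (5, 10, 20, 40, 80, 160, 320, 640, 1280, 1440)
METHODS = ("phase_dependent", "linear", "global_median", "zero")

#: Default policies mirroring short-gap interpolation / long-gap phase
#: filling: linear for MET gaps <= 40 min, <= 320 min for sleep state.
DEFAULT_MET_BREAKPOINT = 40
DEFAULT_STATE_BREAKPOINT = 320


@dataclass
class FillPolicy:
    """Gap-length -> method mapping over a grid of gap lengths.

    For a real gap whose length falls between grid points, the method of
    the smallest grid length >= the gap length applies (the largest grid
    length for longer gaps).
    """

    methods: Mapping[int, str]

    def __post_init__(self) -> None:
        bad = set(self.methods.values()) - set(METHODS)
        if bad:
            raise ValueError(f"unknown fill methods: {sorted(bad)}")
        self._grid = sorted(self.methods)

    @classmethod
    def from_breakpoint(cls, breakpoint: int = DEFAULT_MET_BREAKPOINT,
                        grid: Sequence[int] = GAP_GRID) -> "FillPolicy":
        return cls({g: ("linear" if g <= breakpoint else "phase_dependent")
                    for g in grid})

    def method_for(self, gap_length: int) -> str:
        for g in self._grid:
            if gap_length <= g:
                return self.methods[g]
        return self.methods[self._grid[-1]]


@dataclass
class MedianWeek:
    """7 x 1440 grid of median values for one half of a participant's data."""

    grid: np.ndarray  # shape (7, 1440), Monday = row 0
    half: str  # "first" | "second"

    def value_at(self, dow: np.ndarray, minute: np.ndarray) -> np.ndarray:
        return self.grid[dow, minute]


def _half_slices(n_days: int) -> dict[str, slice]:
    # first and last floor(days/2) days; an odd middle day joins the first half
    lower = n_days // 2
    return {"first": slice(0, n_days - lower), "second": slice(n_days - lower, n_days)}


def build_median_week(values: pd.Series, half: str) -> MedianWeek:
    """Median-week grid from one half of a minute-indexed series.

    ``values`` must cover whole days on the 1-minute grid.  Raises if the
    chosen half contains no observed values at all.
    """
    if half not in ("first", "second"):
        raise ValueError("half must be 'first' or 'second'")
    n = len(values)
    n_days = n // MINUTES_PER_DAY
    if n_days < 14:
        raise ValueError("median week needs at least 14 days of data")
    sl = _half_slices(n_days)[half]
    day_slice = values.iloc[sl.start * MINUTES_PER_DAY: sl.stop * MINUTES_PER_DAY]
    if day_slice.isna().all():
        raise ValueError(f"{half} half of the data is fully missing")

    dow = day_slice.index.dayofweek.to_numpy()
    minute = (day_slice.index.hour * 60 + day_slice.index.minute).to_numpy()
    frame = pd.DataFrame({"v": day_slice.to_numpy(), "dow": dow, "minute": minute})
    med = frame.groupby(["dow", "minute"], sort=True)["v"].median()

    grid = np.full((7, MINUTES_PER_DAY), np.nan)
    ii = med.index.get_level_values(0).to_numpy()
    jj = med.index.get_level_values(1).to_numpy()
    grid[ii, jj] = med.to_numpy()

    flat = grid.ravel()  # (dow, minute) lexicographic from Monday 00:00
    if np.isnan(flat).any():
        # forward fill in grid order, wrapping from Sunday 23:59 to Monday 00:00
        isnan = np.isnan(flat)
        first_obs = int(np.flatnonzero(~isnan)[0])
        order = np.roll(np.arange(flat.size), -first_obs)
        filled = pd.Series(flat[order]).ffill().to_numpy()
        flat[order] = filled
    return MedianWeek(flat.reshape(7, MINUTES_PER_DAY), half)


def fill_phase_dependent(values: pd.Series,
                         median_weeks: Mapping[str, MedianWeek] | None = None
                         ) -> pd.Series:
    """Fill gaps from the (day-of-week, minute) median-week cell.

    Minutes in the first half of the record use the median week built from
    the first half, likewise the second; this keeps each fill in-sample
    with respect to its own data half.
    """
    if median_weeks is None:
        median_weeks = {h: build_median_week(values, h) for h in ("first", "second")}
    out = values.copy()
    mask = out.isna().to_numpy()
    if not mask.any():
        return out
    n_days = len(values) // MINUTES_PER_DAY
    halves = _half_slices(n_days)
    dow = values.index.dayofweek.to_numpy()
    minute = (values.index.hour * 60 + values.index.minute).to_numpy()
    arr = out.to_numpy(copy=True)
    for half, sl in halves.items():
        lo, hi = sl.start * MINUTES_PER_DAY, sl.stop * MINUTES_PER_DAY
        m = mask.copy()
        m[:lo] = False
        m[hi:] = False
        if m.any():
            arr[m] = median_weeks[half].value_at(dow[m], minute[m])
    out[:] = arr
    return out


def fill_linear(values: pd.Series) -> pd.Series:
    """Linear interpolation with two-way limit direction."""
    if values.notna().sum() == 0:
        raise ValueError("cannot interpolate an all-missing series")
    return values.interpolate(method="linear", limit_direction="both")


def fill_global_median(values: pd.Series) -> pd.Series:
    """Fill every gap with the participant-wide median of observed values."""
    if values.notna().sum() == 0:
        raise ValueError("cannot median-fill an all-missing series")
    return values.fillna(values.median())


def fill_zero(values: pd.Series) -> pd.Series:
    """Fill every gap with 0 (the no-fill equivalent under daily summation)."""
    return values.fillna(0.0)


_FILLERS = {
    "phase_dependent": fill_phase_dependent,
    "linear": fill_linear,
    "global_median": fill_global_median,
    "zero": fill_zero,
}


def fill_with_method(values: pd.Series, method: str) -> pd.Series:
    if method not in _FILLERS:
        raise ValueError(f"unknown fill method {method!r}")
    return _FILLERS[method](values)


def fill_series(series: ActivityTimeSeries, policy: FillPolicy | None = None,
                *, state_policy: FillPolicy | None = None) -> ActivityTimeSeries:
    """Fill a participant's MET and sleep-state gaps under a policy.

    Real gaps are maximal missing runs; each run is filled by the policy's
    method for its length.  Sleep-state gaps are filled on the 0/1 encoding
    (0 = asleep, 1 = awake) and rounded back to labels.
    """
    if policy is None:
        policy = FillPolicy.from_breakpoint(DEFAULT_MET_BREAKPOINT)
    if state_policy is None:
        state_policy = FillPolicy.from_breakpoint(DEFAULT_STATE_BREAKPOINT)
    new = series.copy()
    new.data["met"] = _fill_by_runs(series.met, policy)
    state_num = series.state_numeric()
    if state_num.isna().any():
        filled = _fill_by_runs(state_num, state_policy)
        rounded = np.clip(np.round(filled.to_numpy()), 0, 1)
        new.data["state"] = pd.Categorical(
            np.where(rounded == 1.0, "awake", "asleep"),
            categories=["awake", "asleep"])
    return new


def _fill_by_runs(values: pd.Series, policy: FillPolicy) -> pd.Series:
    mask = values.isna().to_numpy()
    if not mask.any():
        return values.copy()
    runs = _missing_runs(mask)
    needed = {policy.method_for(length) for _, length in runs}
    filled = {m: fill_with_method(values, m) for m in needed}
    out = values.copy()
    arr = out.to_numpy(copy=True)
    for start, length in runs:
        m = policy.method_for(length)
        arr[start:start + length] = filled[m].to_numpy()[start:start + length]
    out[:] = arr
    return out


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class FillEvaluation:
    """Simulated-missingness evaluation results.

    ``table`` has one row per (participant, method, gap_length) with the
    summed absolute error over determinate test indices and the count of
    indeterminate indices (true value itself missing).
    """

    table: pd.DataFrame
    kind: str = "met"

    def totals(self) -> pd.DataFrame:
        """Error summed across participants, per (method, gap_length)."""
        return (self.table.groupby(["method", "gap_length"], as_index=False)
                ["error"].sum())

    def indeterminate_fraction(self) -> float:
        per = self.table.groupby(["participant_id", "gap_length"]).first()
        tot_injected = per["n_test"].sum() + per["indeterminate"].sum()
        return float(per["indeterminate"].sum() / tot_injected) if tot_injected else 0.0


def evaluate_fillers(cohort: Sequence[ActivityTimeSeries],
                     gap_grid: Sequence[int] = GAP_GRID,
                     seed: int = 0, *, kind: str = "met",
                     ) -> tuple[FillEvaluation, FillPolicy]:
    """Score the four fillers on injected gaps and select a policy.

    One gap of each grid length is injected per participant at a uniformly
    random start (overlaps permitted); every method fills the gapped series
    and is scored by the summed absolute difference to the held-out truth.
    For ``kind="state"`` the 0/1 sleep-state series is evaluated and
    predictions are rounded to {0, 1} before scoring.  The best method per
    gap length (smallest total error; ties broken phase_dependent > linear
    > global_median > zero) forms the returned policy.
    """
    if kind not in ("met", "state"):
        raise ValueError("kind must be 'met' or 'state'")
    rows = []
    rng = np.random.default_rng(seed)
    for ats in cohort:
        truth_full = ats.met if kind == "met" else ats.state_numeric()
        gapped, injected = inject_missingness(
            ats, [(g, 1) for g in gap_grid], seed=int(rng.integers(2**31)))
        test = gapped.met if kind == "met" else gapped.state_numeric()
        truth = truth_full.to_numpy()
        filled = {}
        for method in METHODS:
            pred = fill_with_method(test, method).to_numpy()
            if kind == "state":
                pred = np.clip(np.round(pred), 0, 1)
            filled[method] = pred
        for g in gap_grid:
            idx = injected[g]
            ok = ~np.isnan(truth[idx])
            n_ind = int((~ok).sum())
            use = idx[ok]
            for method in METHODS:
                err = float(np.abs(filled[method][use] - truth[use]).sum())
                rows.append({"participant_id": ats.participant_id,
                             "method": method, "gap_length": int(g),
                             "error": err, "n_test": int(ok.sum()),
                             "indeterminate": n_ind})
    evaluation = FillEvaluation(pd.DataFrame(rows), kind=kind)
    totals = evaluation.totals()
    pref = {m: i for i, m in enumerate(METHODS)}
    best = {}
    for g in gap_grid:
        sub = totals[totals["gap_length"] == g]
        sub = sub.assign(_pref=sub["method"].map(pref)).sort_values(
            ["error", "_pref"])
        best[int(g)] = sub.iloc[0]["method"]
    return evaluation, FillPolicy(best)
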