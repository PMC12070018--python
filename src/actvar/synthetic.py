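"""Synthetic minute-level MET cohort generator with known ground truth.

Emulates the structure of a wearable-device activity study: 1-minute MET
sampling over hundreds of days, a nightly sleep period, awake-rest values in
[1.0, 1.5], intentional-exercise bouts above 1.5, a hard floor of 0.9
(the sleeping metabolic rate reported by the device), day-of-week activity
phenotypes (weekend-high / weekend-low / patternless), sex- and
age-dependent day-to-day dispersion, and missingness in contiguous gaps.

The day-to-day dispersion is controlled through the consecutive disparity
index (CDI) of daily 24-hour MET sums.  Daily sums are drawn lognormal
around a participant's latent level; for iid log-normal days with log-SD
``sigma`` the expected CDI is ``2*sigma/sqrt(pi)`` (the mean of a
half-normal), so ``sigma_for_cdi`` inverts that in closed form.  Because
each day's minute trace is scaled to hit its drawn daily sum exactly, the
realized CDI of a participant's daily sums matches the target up to
sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .series import ASLEEP, AWAKE, MINUTES_PER_DAY, ActivityTimeSeries, minute_grid

SEXES = ("female", "male")
AGE_BINS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
PHENOTYPES = ("weekend_high", "weekend_low", "patternless")

#: Default target CDI of daily 24-h MET sums by (sex, age bin) —
#: female dispersion lower than male, declining in the oldest decades.
DEFAULT_TARGET_CDI: dict = {
    ("female", "20-29"): 0.082, ("female", "30-39"): 0.080,
    ("female", "40-49"): 0.074, ("female", "50-59"): 0.084,
    ("female", "60-69"): 0.068, ("female", "70-79"): 0.062,
    ("male", "20-29"): 0.087, ("male", "30-39"): 0.096,
    ("male", "40-49"): 0.091, ("male", "50-59"): 0.100,
    ("male", "60-69"): 0.081, ("male", "70-79"): 0.076,
    "default": 0.085,
}

#: Cyclic-status prevalence by (sex, age bin): essentially confined to
#: female participants under 60.
DEFAULT_CYCLIC_FRACTION: dict = {
    ("female", "20-29"): 0.68, ("female", "30-39"): 0.68,
    ("female", "40-49"): 0.68, ("female", "50-59"): 0.06,
}


def sigma_for_cdi(target_cdi: float) -> float:
    """Day-to-day log-SD that yields the requested CDI for iid lognormal days."""
    if target_cdi < 0:
        raise ValueError("target CDI must be nonnegative")
    return target_cdi * math.sqrt(math.pi) / 2.0


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    Proportion maps must each sum to 1.  ``target_cdi_by_group`` is resolved
    per participant with the most specific matching key first:
    ``(sex, age_bin)``, then ``sex``, then weekend phenotype, then
    ``"default"``.  ``missingness`` is a list of
    ``(gap_length_minutes, expected_count_per_participant)`` pairs; realized
    counts are Poisson so the mask matches the requested structure in
    expectation.
    """

    n_participants: int = 100
    days: int = 206
    start_date: str = "2020-04-01"
    sex_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.5, "male": 0.5})
    age_bin_fractions: Mapping[str, float] = field(
        default_factory=lambda: {b: 1 / 6 for b in AGE_BINS})
    cyclic_fraction_by_sex_age: Mapping = field(
        default_factory=lambda: dict(DEFAULT_CYCLIC_FRACTION))
    weekend_phenotype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"weekend_high": 0.223, "weekend_low": 0.082,
                                 "patternless": 0.695})
    weekend_amplitude: float = 0.3
    target_cdi_by_group: Mapping = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CDI))
    #: light default gap mix (~1% of minutes): many short device dropouts,
    #: a few multi-hour gaps, about one full missing day
    missingness: Sequence[tuple[int, float]] = field(
        default_factory=lambda: [(5, 60), (30, 20), (240, 4), (1440, 1)])
    #: latent daily-sum level: median and interindividual log-SD
    daily_sum_median: float = 1800.0
    daily_sum_log_sd: float = 0.05
    #: between-person SD of the CDI target around its group value (people in
    #: the same demographic group differ in how regular their days are);
    #: set 0 for exactly-on-target groups
    cdi_between_person_sd: float = 0.015
    #: optional 28-day sinusoidal modulation of daily sums for cyclic
    #: participants (fractional amplitude; 0 disables, the default)
    cyclic_effect_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.days < 2:
            raise ValueError("days must be >= 2")
        if self.days * MINUTES_PER_DAY > 2**31:
            raise ValueError("days x 1440 overflows the index range")
        for name, fracs in (("sex_fractions", self.sex_fractions),
                            ("age_bin_fractions", self.age_bin_fractions),
                            ("weekend_phenotype_fractions",
                             self.weekend_phenotype_fractions)):
            vals = list(fracs.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ValueError(f"{name}: proportions must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name}: proportions must sum to 1")
        for length, count in self.missingness:
            if int(length) != length or length <= 0:
                raise ValueError("gap lengths must be positive integers")
            if count < 0:
                raise ValueError("gap counts must be nonnegative")

    def resolve_target_cdi(self, sex: str, age_bin: str, phenotype: str) -> float:
        for key in ((sex, age_bin), sex, phenotype, "default"):
            if key in self.target_cdi_by_group:
                return float(self.target_cdi_by_group[key])
        raise KeyError("target_cdi_by_group has no applicable entry "
                       f"for ({sex}, {age_bin}, {phenotype}) and no 'default'")


def _allocate(labels: Sequence[str], fractions: Mapping[str, float],
              n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n items to labels, then shuffled."""
    raw = np.array([fractions.get(lab, 0.0) for lab in labels]) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    out = np.repeat(np.array(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def _nightly_sleep(rng: np.random.Generator, days: int):
    """Sleep onset (minute of day) and duration for nights -1 .. days-1."""
    n = days + 1
    onset = np.clip(np.round(1380 + rng.uniform(-60, 60, n)), 1321, 1439).astype(int)
    dur = np.round(450 + rng.uniform(-45, 45, n)).astype(int)
    return onset, dur


def _asleep_mask(onset: np.ndarray, dur: np.ndarray, days: int) -> np.ndarray:
    mask = np.zeros((days, MINUTES_PER_DAY), dtype=bool)
    # night index d is the night beginning on the evening of day d-1, so it
    # spills into the morning of day d; night d+1 starts in day d's evening
    for d in range(days):
        morning_end = onset[d] + dur[d] - MINUTES_PER_DAY
        if morning_end > 0:
            mask[d, :min(morning_end, MINUTES_PER_DAY)] = True
        mask[d, onset[d + 1]:] = True
    return mask


def _simulate_participant(rng: np.random.Generator, days: int,
                          weekend_mask_by_day: np.ndarray, phenotype: str,
                          amplitude: float, sigma: float, base_level: float,
                          cyclic: bool, cyclic_amp: float):
    """Minute-level MET array (days x 1440), asleep mask and sleep table."""
    onset, dur = _nightly_sleep(rng, days)
    asleep = _asleep_mask(onset, dur, days)

    met = np.full((days, MINUTES_PER_DAY), 0.9)
    # sleep movement: occasional minutes above the 0.9 sleeping floor
    move = asleep & (rng.random(asleep.shape) < 0.04)
    met[move] = np.minimum(0.9 + rng.exponential(0.25, int(move.sum())), 2.5)
    asleep_sum = np.where(asleep, met, 0.0).sum(axis=1)

    # awake activity shape: diurnal profile + smooth noise + exercise bouts
    minutes = np.arange(MINUTES_PER_DAY)
    diurnal = 0.25 * (1 + np.sin(2 * np.pi * (minutes - 270) / MINUTES_PER_DAY))
    noise = uniform_filter1d(rng.standard_normal((days, MINUTES_PER_DAY)),
                             size=30, axis=1, mode="wrap") * 1.1
    u = np.clip(diurnal[None, :] + noise, 0.01, None)

    bout_rate = np.full(days, 0.6)
    if phenotype == "weekend_high":
        bout_rate[weekend_mask_by_day] *= 1.5
    elif phenotype == "weekend_low":
        bout_rate[weekend_mask_by_day] *= 0.5
    n_bouts = np.minimum(rng.poisson(bout_rate), 2)
    for d in np.nonzero(n_bouts)[0]:
        for _ in range(n_bouts[d]):
            start = rng.integers(480, 1320)
            length = rng.integers(20, 61)
            u[d, start:start + length] += rng.uniform(2, 6)

    # target daily sums: lognormal with weekend shift, hit exactly by scaling
    shift = np.zeros(days)
    if phenotype == "weekend_high":
        shift[weekend_mask_by_day] = math.log1p(amplitude)
    elif phenotype == "weekend_low":
        shift[weekend_mask_by_day] = -math.log1p(amplitude)
    if cyclic and cyclic_amp > 0:
        shift = shift + cyclic_amp * np.sin(2 * np.pi * np.arange(days) / 28.0)
    target = np.exp(math.log(base_level) + shift + rng.normal(0, sigma, days))

    awake = ~asleep
    n_awake = awake.sum(axis=1)
    u_awake = np.where(awake, u, 0.0)
    u_sum = u_awake.sum(axis=1)
    floor = asleep_sum + n_awake + 0.02 * u_sum
    target = np.maximum(target, floor)
    gain = (target - asleep_sum - n_awake) / u_sum
    met = np.where(awake, 1.0 + gain[:, None] * u_awake, met)

    sleep_table = pd.DataFrame({
        "night": np.arange(-1, days),
        "onset_minute": onset,
        "duration_min": dur,
    })
    return met, asleep, sleep_table


def generate_cohort(spec: CohortSpec):
    """Generate a cohort of :class:`ActivityTimeSeries` with ground truth.

    Returns ``(series_list, metadata, ground_truth)`` where ``metadata`` has
    columns ``participant_id, sex, age_years, age_bin, cyclic`` and
    ``ground_truth`` additionally records each participant's weekend
    phenotype and latent daily-sum parameters.  Identical ``spec`` (including
    the seed) yields bit-identical output.
    """
    spec.validate()
    n = spec.n_participants
    master = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
    children = np.random.SeedSequence([int(spec.seed), 0xC1]).spawn(n)

    sexes = _allocate(SEXES, spec.sex_fractions, n, master)
    ages = np.empty(n, dtype=object)
    for sex in SEXES:
        idx = np.nonzero(sexes == sex)[0]
        ages[idx] = _allocate(AGE_BINS, spec.age_bin_fractions, len(idx), master)
    phen = _allocate(PHENOTYPES, spec.weekend_phenotype_fractions, n, master)
    cyc = np.array([
        master.random() < float(spec.cyclic_fraction_by_sex_age.get(
            (sexes[i], ages[i]), spec.cyclic_fraction_by_sex_age.get(sexes[i], 0.0)))
        for i in range(n)
    ])

    grid = minute_grid(pd.Timestamp(spec.start_date), spec.days)
    dates = pd.date_range(pd.Timestamp(spec.start_date), periods=spec.days, freq="D")
    weekend_by_day = np.asarray(dates.dayofweek.isin([5, 6]))

    series: list[ActivityTimeSeries] = []
    meta_rows, gt_rows, sleep_frames = [], [], []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        pid = f"P{i:04d}"
        target_cdi = spec.resolve_target_cdi(sexes[i], ages[i], phen[i])
        if spec.cdi_between_person_sd > 0:
            target_cdi = max(0.02, target_cdi
                             + rng.normal(0, spec.cdi_between_person_sd))
        sigma = sigma_for_cdi(target_cdi)
        base = float(np.exp(math.log(spec.daily_sum_median)
                            + rng.normal(0, spec.daily_sum_log_sd)))
        met, asleep, sleep_table = _simulate_participant(
            rng, spec.days, weekend_by_day, phen[i], spec.weekend_amplitude,
            sigma, base, bool(cyc[i]), spec.cyclic_effect_amplitude)

        state = pd.Categorical.from_codes(
            asleep.ravel().astype(np.int8), categories=[AWAKE, ASLEEP])
        df = pd.DataFrame({"met": met.ravel(), "state": state}, index=grid)
        ats = ActivityTimeSeries(pid, df)
        if spec.missingness:
            gaps = [(int(length), int(rng.poisson(count)))
                    for length, count in spec.missingness]
            ats, _ = inject_missingness(ats, gaps, seed=rng.integers(2**31))
        series.append(ats)

        lo, hi = (int(x) for x in ages[i].split("-"))
        meta_rows.append({"participant_id": pid, "sex": sexes[i],
                          "age_years": int(rng.integers(lo, hi + 1)),
                          "age_bin": ages[i], "cyclic": bool(cyc[i])})
        gt_rows.append({"participant_id": pid, "sex": sexes[i], "age_bin": ages[i],
                        "cyclic": bool(cyc[i]), "weekend_phenotype": phen[i],
                        "latent_daily_mean": base, "latent_log_sd": sigma,
                        "target_cdi": target_cdi})
        st = sleep_table.copy()
        st.insert(0, "participant_id", pid)
        sleep_frames.append(st)

    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(gt_rows)
    ground_truth.attrs["sleep_tables"] = pd.concat(sleep_frames, ignore_index=True)
    return series, metadata, ground_truth


def sleep_summary_table(ground_truth: pd.DataFrame, start_date,
                        days: int) -> pd.DataFrame:
    """Per-night sleep summary (participant_id, date, sleep_start, sleep_end)
    recoverable from a generated cohort, for the file-based ingestion path."""
    tables = ground_truth.attrs.get("sleep_tables")
    if tables is None:
        raise ValueError("ground truth carries no sleep tables")
    start = pd.Timestamp(start_date).normalize()
    out = tables.copy()
    night_day = start + pd.to_timedelta(out["night"], unit="D")
    out["sleep_start"] = night_day + pd.to_timedelta(out["onset_minute"], unit="min")
    out["sleep_end"] = out["sleep_start"] + pd.to_timedelta(out["duration_min"], unit="min")
    # report the interval on the day it starts
    out["date"] = out["sleep_start"].dt.normalize()
    return out[["participant_id", "date", "sleep_start", "sleep_end"]]


def inject_missingness(series: ActivityTimeSeries,
                       gaps: Sequence[tuple[int, int]],
                       seed: int):
    """Insert contiguous missing runs at uniformly random start minutes.

    Runs may overlap each other and pre-existing gaps; observed values
    elsewhere are untouched.  Returns ``(new_series, injected)`` where
    ``injected`` maps each gap length to the (deduplicated, sorted) array of
    injected integer positions for that length.
    """
    n = series.n_minutes
    rng = np.random.default_rng(seed)
    injected: dict[int, np.ndarray] = {}
    new = series.copy()
    for length, count in gaps:
        length = int(length)
        if length <= 0:
            raise ValueError("gap length must be positive")
        if length > n:
            raise ValueError(f"gap of {length} min longer than series ({n} min)")
        pos: list[np.ndarray] = []
        for _ in range(int(count)):
            start = int(rng.integers(0, n - length + 1))
            pos.append(np.arange(start, start + length))
        injected[length] = (np.unique(np.concatenate(pos)) if pos
                            else np.empty(0, dtype=int))
    all_idx = (np.unique(np.concatenate([v for v in injected.values() if len(v)]))
               if any(len(v) for v in injected.values()) else np.empty(0, dtype=int))
    if len(all_idx):
        met = new.data["met"].to_numpy(copy=True)
        met[all_idx] = np.nan
        new.data["met"] = met
        state = new.data["state"].copy()
        state[new.data.index[all_idx]] = np.nan
        new.data["state"] = state
    return new, injected


def write_cohort(series, metadata: pd.DataFrame, ground_truth: pd.DataFrame,
                 outdir, fmt: str = "csv") -> None:
    """Serialize a cohort: one minute-level file per participant plus
    metadata, ground-truth and sleep-summary tables."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "participants").mkdir(parents=True, exist_ok=True)
    for ats in series:
        df = ats.data.reset_index(names="timestamp")
        path = outdir / "participants" / f"{ats.participant_id}.{fmt}"
        if fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            df.to_csv(path, index=False)
    metadata.to_csv(outdir / "metadata.csv", index=False)
    gt = ground_truth.drop(columns=[], errors="ignore")
    gt.to_csv(outdir / "ground_truth.csv", index=False)
    start = series[0].start if series else pd.Timestamp("2020-04-01")
    days = series[0].n_days if series else 0
    sleep_summary_table(ground_truth, start, days).to_csv(
        outdir / "sleep_summary.csv", index=False)
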