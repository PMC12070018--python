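"""Intraindividual variability metrics and the modified Cohen d effect size.

For a daily-sum series p_1..p_n:

* CV  = sigma / mean (sample SD over mean);
* PV  = mean over all unordered pairs of 1 - min(p_i, p_j)/max(p_i, p_j);
* CDI = mean of |ln(p_{i+1}/p_i)| over consecutive pairs — order-sensitive,
  mean-independent and scale-invariant, which makes it the preferred
  intraindividual variability statistic for activity time series.

The modified Cohen d compares two skewed samples by
|median(P1) - median(P2)| / mean(IQR(P1), IQR(P2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _check_series(x: np.ndarray, positive: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-D with at least 2 values")
    if np.isnan(x).any():
        raise ValueError("series contains missing values")
    if positive and (x <= 0).any():
        raise ValueError("series values must be strictly positive")
    return x


def cv(series) -> float:
    """Coefficient of variation: sample SD divided by the mean."""
    x = _check_series(series, positive=False)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    return float(x.std(ddof=1) / m)


def pv(series) -> float:
    """Proportional variability: mean pairwise 1 - min/max."""
    x = _check_series(series, positive=True)
    n = len(x)
    xi, xj = np.meshgrid(x, x, indexing="ij")
    ratio = np.minimum(xi, xj) / np.maximum(xi, xj)
    # full matrix counts each unordered pair twice and the diagonal (=1) once
    total = (1.0 - ratio).sum()
    return float(total / (n * (n - 1)))


def cdi(series) -> float:
    """Consecutive disparity index: mean |ln(p_{i+1}/p_i)|."""
    x = _check_series(series, positive=True)
    return float(np.mean(np.abs(np.diff(np.log(x)))))


@dataclass
class EffectSize:
    d_m: float
    median1: float
    median2: float
    iqr1: float
    iqr2: float


def iqr(sample) -> float:
    """Interquartile range (75th - 25th percentile, linear interpolation)."""
    x = np.asarray(sample, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def cohen_dm(p1, p2) -> EffectSize:
    """Modified Cohen d: |median difference| over the mean of the IQRs."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    i1, i2 = iqr(a), iqr(b)
    if i1 == 0 and i2 == 0:
        raise ValueError("both IQRs are zero; effect size undefined")
    m1, m2 = float(np.median(a)), float(np.median(b))
    return EffectSize(abs(m1 - m2) / ((i1 + i2) / 2.0), m1, m2, i1, i2)


def variability_profile(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-state variability table.

    ``daily`` is a stacked daily-summary frame (see
    :func:`actvar.summaries.summarize_cohort`).  Returns one row per
    (participant, state) with mean, sd, cv, pv and cdi of the daily sums,
    ordered by date within participant.
    """
    cols = {"24h": "sum_24h", "awake": "sum_awake", "asleep": "sum_asleep"}
    rows = []
    for pid, g in daily.sort_values("date").groupby("participant_id", sort=True):
        for state, col in cols.items():
            v = g[col].to_numpy()
            positive = bool((v > 0).all())
            rows.append({
                "participant_id": pid, "state": state,
                "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                "cv": cv(v) if v.mean() > 0 else np.nan,
                # ratio-based metrics are undefined on nonpositive sums
                # (e.g. a state never entered on some day)
                "pv": pv(v) if positive else np.nan,
                "cdi": cdi(v) if positive else np.nan,
            })
    return pd.DataFrame(rows)
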