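"""Weekly activity-rhythm detection.

Daily 24-hour MET sums over a common 4-consecutive-calendar-month window
are z-scored within each individual (so rhythms are compared regardless of
baseline activity), transformed to the bounded relative-activity scale
arctan(2 z) for display, and Ward-linkage agglomerative clustering into
five groups separates individuals whose weekend days are systematically
high or low relative to their own weekdays from the patternless majority.

Cluster labels: the mean weekend-minus-weekday z contrast of a cluster's
members decides its rhythm label — above +``threshold`` z-units is
``weekend_high``, below -``threshold`` is ``weekend_low``, otherwise
``patternless``.  The threshold replaces the visual heat-map read-off used
in exploratory work with a reproducible rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .inference import GroupComparison, compare_groups
from .metrics import cdi

log = logging.getLogger(__name__)

WEEKEND_DAYS = (5, 6)  # Saturday, Sunday
DEFAULT_CONTRAST_THRESHOLD = 0.25
RHYTHM_LABELS = ("weekend_high", "weekend_low", "patternless")


def select_window(dates, n_months: int = 4, *,
                  allow_shorter: bool = False) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First ``n_months`` fully covered consecutive calendar months.

    ``dates`` is the set of study days (any iterable of datetimes).  A month
    is fully covered when every one of its calendar days is present.
    Returns (first_day, last_day) of the window, inclusive.  With
    ``allow_shorter`` the requirement degrades gracefully (fewer months,
    finally the whole date range) for short records.
    """
    idx = pd.DatetimeIndex(pd.unique(pd.DatetimeIndex(dates).normalize())).sort_values()
    periods = idx.to_period("M")
    full_months = []
    for per in periods.unique():
        n_in = int((periods == per).sum())
        if n_in == per.days_in_month:
            full_months.append(per)
    for i in range(len(full_months) - n_months + 1):
        run = full_months[i:i + n_months]
        if all((run[j + 1] - run[j]).n == 1 for j in range(n_months - 1)):
            start = run[0].to_timestamp()
            end = run[-1].to_timestamp(how="end").normalize()
            return start, end
    if allow_shorter:
        if n_months > 1:
            return select_window(idx, n_months - 1, allow_shorter=True)
        log.warning("no fully covered calendar month; using the whole range")
        return idx[0], idx[-1]
    raise ValueError(f"no run of {n_months} fully covered consecutive months")


@dataclass
class RelativeActivityMatrix:
    """Per-individual z-scores of daily 24-h sums over the common window."""

    z: pd.DataFrame           # participants x days
    transformed: pd.DataFrame  # arctan(2 z)
    window: tuple[pd.Timestamp, pd.Timestamp]

    @property
    def weekend_columns(self) -> np.ndarray:
        return np.asarray(self.z.columns.dayofweek.isin(WEEKEND_DAYS))


def zscore_daily(daily: pd.DataFrame,
                 window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
                 ) -> RelativeActivityMatrix:
    """Intraindividual z-scores of daily 24-h MET sums on a common window.

    ``daily`` is a stacked daily-summary frame (must be gap-free over the
    window for every participant).  Constant rows map to all-zeros with a
    warning.  The companion matrix holds arctan(2 z).
    """
    if window is None:
        window = select_window(daily["date"], allow_shorter=True)
    start, end = window
    sub = daily[(daily["date"] >= start) & (daily["date"] <= end)]
    wide = sub.pivot(index="participant_id", columns="date", values="sum_24h")
    if wide.isna().any().any():
        raise ValueError("window not fully covered for every participant")
    arr = wide.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("%d constant row(s) mapped to all-zero z-scores", flat.sum())
        sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    zdf = pd.DataFrame(z, index=wide.index, columns=wide.columns)
    return RelativeActivityMatrix(zdf, np.arctan(2 * zdf), window)


def cluster_agglomerative(matrix: RelativeActivityMatrix, k: int = 5) -> pd.Series:
    """Ward/Euclidean agglomerative clustering of the z-score rows.

    Returns a Series of integer cluster ids (0..k-1) indexed by
    participant id.  The partition is deterministic.
    """
    z = matrix.z
    if k > len(z):
        raise ValueError(f"k={k} exceeds the number of participants ({len(z)})")
    if k == 1:
        labels = np.zeros(len(z), dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = model.fit_predict(z.to_numpy())
    return pd.Series(labels, index=z.index, name="cluster_id")


def label_weekend_rhythm(assignment: pd.Series, matrix: RelativeActivityMatrix,
                         threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                         ) -> pd.DataFrame:
    """Derive weekend-rhythm labels from per-cluster weekend z contrast.

    Returns a frame with ``participant_id, cluster_id, rhythm_label,
    weekend_contrast`` (the contrast is the cluster-level value every member
    inherits).
    """
    wk = matrix.weekend_columns
    if not wk.any():
        raise ValueError("window contains no weekend days")
    z = matrix.z.to_numpy()
    rows = []
    contrasts = {}
    for cid in np.unique(assignment.to_numpy()):
        members = assignment[assignment == cid].index
        sub = matrix.z.loc[members].to_numpy()
        contrast = float(sub[:, wk].mean() - sub[:, ~wk].mean())
        if contrast > threshold:
            label = "weekend_high"
        elif contrast < -threshold:
            label = "weekend_low"
        else:
            label = "patternless"
        contrasts[cid] = (label, contrast)
    del z
    for pid, cid in assignment.items():
        label, contrast = contrasts[cid]
        rows.append({"participant_id": pid, "cluster_id": int(cid),
                     "rhythm_label": label, "weekend_contrast": contrast})
    return pd.DataFrame(rows)


def assign_weekend_rhythm(daily: pd.DataFrame, k: int = 5,
                          threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                          window=None) -> pd.DataFrame:
    """Convenience pipeline: z-score, cluster into ``k`` groups, label."""
    matrix = zscore_daily(daily, window)
    assignment = cluster_agglomerative(matrix, k)
    return label_weekend_rhythm(assignment, matrix, threshold)


def rhythm_group_stats(daily: pd.DataFrame, labels: pd.DataFrame,
                       metadata: pd.DataFrame | None = None,
                       window=None) -> dict[str, GroupComparison]:
    """Group comparisons of window-restricted means and CDIs by rhythm.

    Per individual, the mean and CDI of daily 24-h sums are computed over
    the clustering window only.  Comparisons follow the analysis design:
    means across the three rhythm labels (Bonferroni for 3 comparisons),
    CDI between {any weekend rhythm} and patternless (two groups), and —
    when ``metadata`` with a ``sex`` column is given — CDI across the four
    sex x rhythm-presence cells (Bonferroni for 6 comparisons).  Empty
    label classes skip their comparison with a warning.
    """
    if window is None:
        window = select_window(daily["date"], allow_shorter=True)
    start, end = window
    sub = daily[(daily["date"] >= start) & (daily["date"] <= end)].sort_values("date")
    per = sub.groupby("participant_id")["sum_24h"].agg(
        mean="mean", cdi=lambda v: cdi(v.to_numpy()))
    table = per.join(labels.set_index("participant_id")["rhythm_label"])
    table["rhythm_presence"] = np.where(table["rhythm_label"] == "patternless",
                                        "patternless", "weekend_rhythm")
    out: dict[str, GroupComparison] = {}

    present = table["rhythm_label"].value_counts()
    if all(present.get(lbl, 0) > 0 for lbl in RHYTHM_LABELS):
        out["mean_by_rhythm"] = compare_groups(
            table["mean"], table["rhythm_label"], n_comparisons=3)
    else:
        log.warning("empty rhythm class; skipping mean comparison")

    if table["rhythm_presence"].nunique() == 2:
        out["cdi_by_rhythm_presence"] = compare_groups(
            table["cdi"], table["rhythm_presence"], n_comparisons=1)
    else:
        log.warning("only one rhythm-presence class; skipping CDI comparison")

    if metadata is not None and "sex" in metadata.columns:
        cells = table.join(metadata.set_index("participant_id")["sex"])
        cells["cell"] = cells["sex"] + "/" + cells["rhythm_presence"]
        if cells["cell"].nunique() >= 2:
            out["cdi_by_sex_rhythm"] = compare_groups(
                cells["cdi"], cells["cell"], n_comparisons=6)
    return out
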