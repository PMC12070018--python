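"""Nonparametric group-comparison protocol and power accounting.

The protocol: a Kruskal-Wallis H omnibus test between group distributions;
the significance threshold 0.05 divided by the number of planned
comparisons (Bonferroni); when the omnibus test passes with more than two
groups, a post hoc Dunn test identifies the significant pairs; the modified
Cohen d effect size is reported only for those pairs, with the larger-median
group named.

Also here: the daily-IQR subpopulation-variability test (does removing a
subgroup shrink the day-by-day cross-sectional spread of the population?)
and Lehr's sample-size rule n = 16 s^2 / (mu1 - mu2)^2.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import EffectSize, cohen_dm, iqr

log = logging.getLogger(__name__)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    If every value in every group is identical the statistic is degenerate;
    (0.0, 1.0) is returned with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    allv = np.concatenate(groups)
    if len(allv) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(allv == allv[0]):
        warnings.warn("all values identical across groups; H set to 0")
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups) -> pd.DataFrame:
    """Pairwise two-sided Dunn z-test p-values with tie correction.

    Groups are rank-compared on the pooled midranks; the variance term is
    N(N+1)/12 - sum(t^3 - t)/(12(N-1)) with t the tie multiplicities.  No
    internal multiplicity adjustment is applied: in this protocol the
    Bonferroni correction operates at the omnibus layer.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("Dunn test requires non-empty groups")
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)])

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    var = n * (n + 1) / 12.0 - tie_term

    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            pij = 1.0
        else:
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = 2.0 * stats.norm.sf(z)
        pmat[i, j] = pmat[j, i] = pij
    return pd.DataFrame(pmat)


@dataclass
class GroupComparison:
    """Result of the omnibus + post hoc + effect-size protocol."""

    groups: list
    h: float
    p: float
    alpha_corrected: float
    significant: bool
    dunn_p: pd.DataFrame | None = None
    effect_sizes: dict = field(default_factory=dict)
    larger_median: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)


def compare_groups(values, labels, n_comparisons: int = 1,
                   alpha: float = 0.05) -> GroupComparison:
    """Run the full comparison protocol on a labeled sample.

    ``values`` and ``labels`` are aligned sequences; ``n_comparisons`` is
    the Bonferroni denominator of the analysis family this comparison
    belongs to.  Effect sizes (modified Cohen d) are computed only for
    significant pairs, with the larger-median group named per pair.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [str(x) for x in pd.unique(labels)]
    grouped = {name: values[labels == name] for name in names}
    if any(len(v) == 0 for v in grouped.values()):
        raise ValueError("every label must have at least one observation")
    h, p = kruskal_wallis(list(grouped.values()))
    alpha_corr = alpha / n_comparisons
    sig = p < alpha_corr
    medians = {name: float(np.median(v)) for name, v in grouped.items()}
    result = GroupComparison(names, h, p, alpha_corr, sig, medians=medians)
    if not sig:
        return result
    if len(names) > 2:
        dunn = dunn_posthoc(list(grouped.values()))
        dunn.index = dunn.columns = names
        result.dunn_p = dunn
        sig_pairs = [(a, b) for a, b in itertools.combinations(names, 2)
                     if dunn.loc[a, b] < alpha_corr]
    else:
        sig_pairs = [tuple(names)]
    for a, b in sig_pairs:
        try:
            es = cohen_dm(grouped[a], grouped[b])
        except ValueError:
            continue
        result.effect_sizes[(a, b)] = es
        result.larger_median[(a, b)] = a if medians[a] >= medians[b] else b
    return result


@dataclass
class SubpopulationEffect:
    iqr_whole: np.ndarray
    iqr_reduced: np.ndarray
    h: float
    p: float
    #: True when the whole population's daily IQRs are larger (the subgroup
    #: imparts variability) — only meaningful when the test is significant
    whole_larger: bool

    def imparts_variability(self, alpha: float = 0.05) -> bool:
        return self.p < alpha and self.whole_larger


def subpopulation_effect(daily: pd.DataFrame, subgroup_ids) -> SubpopulationEffect:
    """Daily-IQR test of a subgroup's contribution to population variability.

    ``daily`` is a stacked daily-summary frame with ``participant_id``,
    ``date`` and ``sum_24h``.  For each study day, the cross-sectional IQR
    of the whole population and of the population minus the subgroup is
    computed; the two IQR lists (one value per day each) are compared with
    a Kruskal-Wallis test.
    """
    subgroup = set(subgroup_ids)
    all_ids = set(daily["participant_id"].unique())
    if not subgroup <= all_ids:
        raise ValueError("subgroup must be a subset of the cohort")
    if subgroup == all_ids:
        raise ValueError("subgroup equals the whole cohort")
    reduced = daily[~daily["participant_id"].isin(subgroup)]
    iqr_whole = daily.groupby("date")["sum_24h"].apply(iqr).to_numpy()
    iqr_reduced = reduced.groupby("date")["sum_24h"].apply(iqr).to_numpy()
    if len(iqr_whole) != len(iqr_reduced):
        raise ValueError("subgroup removal changed the day set")
    if np.array_equal(iqr_whole, iqr_reduced):
        h, p = 0.0, 1.0
    else:
        h, p = kruskal_wallis([iqr_whole, iqr_reduced])
    whole_larger = float(np.median(iqr_whole)) > float(np.median(iqr_reduced))
    return SubpopulationEffect(iqr_whole, iqr_reduced, h, p, whole_larger)


def lehr_n(s: float, delta: float) -> int:
    """Lehr's rule n = 16 s^2 / delta^2, rounded to the nearest integer.

    ``s`` is the variability proxy (here: the median daily IQR) and
    ``delta`` the target mean difference at 80% power, alpha = 0.05.
    """
    if s <= 0 or delta <= 0:
        raise ValueError("s and delta must be positive")
    n = 16.0 * s * s / (delta * delta)
    return int(math.floor(n + 0.5))


def reduction_pct(n_before: float, n_after: float) -> float:
    """Percentage reduction 100 (n_before - n_after) / n_before, 1 decimal."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    return round(100.0 * (n_before - n_after) / n_before, 1)


def count_pct(part: int, whole: int) -> float:
    """Share of a count in a population as a percentage, 1 decimal."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, 1)
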