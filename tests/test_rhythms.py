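"""Window selection, z-scoring, clustering and weekend-rhythm labeling."""

import numpy as np
import pandas as pd
import pytest

from actvar.rhythms import (
    RelativeActivityMatrix, assign_weekend_rhythm, cluster_agglomerative,
    label_weekend_rhythm, rhythm_group_stats, select_window, zscore_daily,
)


def _daily_frame(matrix, start="2020-05-01"):
    """Long daily-summary frame from a participants x days array."""
    dates = pd.date_range(start, periods=matrix.shape[1])
    rows = []
    for i, row in enumerate(matrix):
        rows.append(pd.DataFrame({"participant_id": f"P{i:03d}",
                                  "date": dates, "sum_24h": row}))
    return pd.concat(rows, ignore_index=True)


class TestSelectWindow:
    def test_first_four_full_months(self):
        dates = pd.date_range("2020-04-01", periods=206)
        start, end = select_window(dates)
        assert start == pd.Timestamp("2020-04-01")
        assert end == pd.Timestamp("2020-07-31")

    def test_partial_leading_month_skipped(self):
        dates = pd.date_range("2020-04-15", periods=206)
        start, _ = select_window(dates)
        assert start == pd.Timestamp("2020-05-01")

    def test_insufficient_months_raise_or_fall_back(self):
        dates = pd.date_range("2020-04-01", periods=80)
        with pytest.raises(ValueError, match="consecutive months"):
            select_window(dates)
        start, end = select_window(dates, allow_shorter=True)
        assert (start, end) == (pd.Timestamp("2020-04-01"),
                                pd.Timestamp("2020-05-31"))


class TestZScore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        daily = _daily_frame(rng.uniform(1000, 2000, (6, 61)))
        mat = zscore_daily(daily, (pd.Timestamp("2020-05-01"),
                                   pd.Timestamp("2020-06-30")))
        z = mat.z.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_row_becomes_zeros(self):
        arr = np.vstack([np.full(61, 1500.0), np.random.default_rng(1)
                         .uniform(1000, 2000, 61)])
        daily = _daily_frame(arr)
        mat = zscore_daily(daily)
        assert (mat.z.iloc[0] == 0).all()

    def test_arctan_transform(self):
        arr = np.random.default_rng(2).uniform(1000, 2000, (3, 61))
        mat = zscore_daily(_daily_frame(arr))
        np.testing.assert_allclose(mat.transformed.to_numpy(),
                                   np.arctan(2 * mat.z.to_numpy()))
        assert np.arctan(2 * 1.0) == pytest.approx(1.1071487)
        assert (np.abs(mat.transformed.to_numpy()) < np.pi / 2).all()

    def test_incomplete_window_rejected(self):
        daily = _daily_frame(np.ones((2, 61)) * 1500)
        daily = daily.iloc[:-1]  # drop one participant-day
        with pytest.raises(ValueError, match="covered"):
            zscore_daily(daily, (pd.Timestamp("2020-05-01"),
                                 pd.Timestamp("2020-06-30")))


def _blob_matrix(seed=0):
    """Two well-separated groups of daily z-profiles."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(1400, 1600, 61)
    a = base + rng.normal(0, 10, (10, 61))
    b = base + 800 * np.sin(np.arange(61) / 3) + rng.normal(0, 10, (10, 61))
    return np.vstack([a, b])


class TestClustering:
    def test_two_blobs_perfect_split(self):
        mat = zscore_daily(_daily_frame(_blob_matrix()))
        labels = cluster_agglomerative(mat, k=2).to_numpy()
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k1_single_cluster(self):
        mat = zscore_daily(_daily_frame(_blob_matrix()))
        assert (cluster_agglomerative(mat, k=1) == 0).all()

    def test_row_permutation_preserves_partition(self):
        from sklearn.metrics import adjusted_rand_score

        arr = _blob_matrix(3)
        daily = _daily_frame(arr)
        mat = zscore_daily(daily)
        base = cluster_agglomerative(mat, k=2)
        perm = np.random.default_rng(4).permutation(arr.shape[0])
        daily_p = _daily_frame(arr[perm])
        # map permuted participant ids back to original rows
        mat_p = zscore_daily(daily_p)
        labels_p = cluster_agglomerative(mat_p, k=2)
        relabeled = [labels_p.iloc[list(perm).index(i)] for i in range(len(perm))]
        assert adjusted_rand_score(base.to_numpy(), relabeled) == 1.0

    def test_k_exceeding_rows_rejected(self):
        mat = zscore_daily(_daily_frame(_blob_matrix()))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_agglomerative(mat, k=100)


class TestWeekendLabeling:
    @staticmethod
    def _weekend_shifted(shift, n=8, seed=0, days=61):
        rng = np.random.default_rng(seed)
        dates = pd.date_range("2020-05-01", periods=days)
        weekend = np.asarray(dates.dayofweek.isin([5, 6]))
        arr = 1500 + rng.normal(0, 30, (n, days))
        arr[:, weekend] += shift
        return arr

    def test_weekend_high_cluster_labeled(self):
        arr = np.vstack([self._weekend_shifted(300, n=6),
                         self._weekend_shifted(0, n=6, seed=1)])
        daily = _daily_frame(arr)
        labels = assign_weekend_rhythm(daily, k=2)
        by_pid = labels.set_index("participant_id")["rhythm_label"]
        assert (by_pid.iloc[:6] == "weekend_high").all()
        assert (by_pid.iloc[6:] == "patternless").all()

    def test_flat_cluster_patternless(self):
        arr = self._weekend_shifted(0, n=6)
        labels = assign_weekend_rhythm(_daily_frame(arr), k=2)
        assert (labels["rhythm_label"] == "patternless").all()

    def test_zero_contrast_boundary_is_patternless(self):
        mat = zscore_daily(_daily_frame(self._weekend_shifted(0, n=5)))
        assignment = pd.Series(np.zeros(5, dtype=int), index=mat.z.index)
        out = label_weekend_rhythm(assignment, mat, threshold=0.0)
        # contrast must exceed the threshold strictly to earn a rhythm label
        flat = RelativeActivityMatrix(mat.z * 0, mat.transformed * 0, mat.window)
        out0 = label_weekend_rhythm(assignment, flat, threshold=0.0)
        assert (out0["rhythm_label"] == "patternless").all()
        assert set(out["rhythm_label"]) <= {"weekend_high", "weekend_low",
                                            "patternless"}

    def test_every_participant_labeled(self):
        arr = np.vstack([self._weekend_shifted(300, n=5),
                         self._weekend_shifted(-300, n=5, seed=2),
                         self._weekend_shifted(0, n=8, seed=3)])
        labels = assign_weekend_rhythm(_daily_frame(arr), k=3)
        assert len(labels) == 18
        assert labels["rhythm_label"].notna().all()


class TestRhythmGroupStats:
    def test_planted_rhythm_has_larger_cdi(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("2020-05-01", periods=122)
        weekend = np.asarray(dates.dayofweek.isin([5, 6]))
        rows = []
        for i in range(40):
            noise_sd = 0.05
            base = 1500 * np.exp(rng.normal(0, noise_sd, 122))
            if i < 15:  # weekend-high participants jump every weekend
                base[weekend] *= 1.4
            rows.append(pd.DataFrame({"participant_id": f"P{i:03d}",
                                      "date": dates, "sum_24h": base}))
        daily = pd.concat(rows, ignore_index=True)
        labels = assign_weekend_rhythm(daily, k=5)
        stats = rhythm_group_stats(daily, labels)
        comp = stats["cdi_by_rhythm_presence"]
        assert comp.significant
        assert comp.medians["weekend_rhythm"] > comp.medians["patternless"]

    def test_all_patternless_skips_mean_comparison(self):
        rng = np.random.default_rng(6)
        arr = 1500 + rng.normal(0, 30, (10, 122))
        daily = _daily_frame(arr)
        labels = assign_weekend_rhythm(daily, k=2)
        assert (labels["rhythm_label"] == "patternless").all()
        stats = rhythm_group_stats(daily, labels)
        assert "mean_by_rhythm" not in stats
        assert "cdi_by_rhythm_presence" not in stats
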