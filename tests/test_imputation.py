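"""Gap fillers: per-method contracts, median-week construction, evaluation."""

import numpy as np
import pandas as pd
import pytest

from actvar.imputation import (
    FillPolicy, MedianWeek, build_median_week, evaluate_fillers,
    fill_global_median, fill_linear, fill_phase_dependent, fill_series,
    fill_with_method, fill_zero,
)
from actvar.series import minute_grid
from actvar.synthetic import CohortSpec, generate_cohort
from conftest import make_series


def _minute_series(values, start="2020-04-06"):
    values = np.asarray(values, dtype=float)
    n_days = int(np.ceil(len(values) / 1440))
    grid = minute_grid(pd.Timestamp(start), n_days)[: len(values)]
    return pd.Series(values, index=grid)


def _weekly_periodic(n_days, start="2020-04-06"):
    """Deterministic series depending only on (day-of-week, minute)."""
    grid = minute_grid(pd.Timestamp(start), n_days)
    dow = grid.dayofweek.to_numpy()
    minute = (grid.hour * 60 + grid.minute).to_numpy()
    return pd.Series(1.0 + dow + np.sin(2 * np.pi * minute / 1440), index=grid)


class TestMedianWeek:
    def test_day_of_week_value_recovered(self):
        grid = minute_grid(pd.Timestamp("2020-04-06"), 14)
        values = pd.Series(grid.dayofweek.astype(float), index=grid)
        mw = build_median_week(values, "first")
        for d in range(7):
            assert (mw.grid[d] == d).all()

    def test_constant_series(self):
        values = _minute_series(np.full(14 * 1440, 1.7))
        for half in ("first", "second"):
            mw = build_median_week(values, half)
            assert (mw.grid == 1.7).all()

    def test_forward_fill_from_preceding_minute(self):
        values = _minute_series(np.full(14 * 1440, 1.3))
        # Monday 09:00 never observed in either week of the first half
        arr = values.to_numpy()
        arr[9 * 60] = np.nan
        arr[7 * 1440 + 9 * 60] = np.nan
        values[:] = arr
        mw = build_median_week(values, "first")
        assert mw.grid[0, 9 * 60] == 1.3  # pulled from Monday 08:59

    def test_empty_half_rejected(self):
        arr = np.full(14 * 1440, 1.0)
        arr[: 7 * 1440] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            build_median_week(_minute_series(arr), "first")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="14 days"):
            build_median_week(_minute_series(np.ones(10 * 1440)), "first")


class TestFillLinear:
    @pytest.mark.parametrize("before,after", [
        ([1, np.nan, 3], [1, 2, 3]),
        ([np.nan, 2, 4], [2, 2, 4]),
        ([1, np.nan, np.nan, 4], [1, 2, 3, 4]),
    ])
    def test_examples(self, before, after):
        out = fill_linear(_minute_series(before))
        np.testing.assert_allclose(out.to_numpy(), after)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            fill_linear(_minute_series([np.nan, np.nan]))

    def test_interior_fills_bounded_by_flanks(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, 500)
        arr = vals.copy()
        holes = rng.choice(np.arange(1, 499), 80, replace=False)
        arr[holes] = np.nan
        out = fill_linear(_minute_series(arr)).to_numpy()
        for h in holes:
            lo = arr[:h][~np.isnan(arr[:h])]
            hi = arr[h + 1:][~np.isnan(arr[h + 1:])]
            assert min(lo[-1], hi[0]) - 1e-12 <= out[h] <= max(lo[-1], hi[0]) + 1e-12


class TestSimpleFillers:
    def test_global_median_examples(self):
        out = fill_global_median(_minute_series([1, 2, 9, np.nan]))
        assert out.iloc[-1] == 2.0
        out = fill_global_median(_minute_series([1, 2, 3, 4, np.nan]))
        assert out.iloc[-1] == 2.5
        out = fill_global_median(_minute_series([7, 7, np.nan]))
        assert out.iloc[-1] == 7.0

    def test_zero_fill(self):
        out = fill_zero(_minute_series([1, np.nan]))
        np.testing.assert_array_equal(out.to_numpy(), [1, 0])
        all_nan = fill_zero(_minute_series([np.nan, np.nan]))
        assert (all_nan == 0).all()

    @pytest.mark.parametrize("method", ["linear", "global_median", "zero"])
    def test_no_gaps_is_identity(self, method):
        values = _minute_series([1.0, 2.0, 3.0])
        out = fill_with_method(values, method)
        np.testing.assert_array_equal(out.to_numpy(), values.to_numpy())


class TestPhaseDependent:
    def test_fills_from_matching_phase(self):
        values = _weekly_periodic(28)
        truth = values.copy()
        arr = values.to_numpy()
        hole = 1440 + 9 * 60  # Tuesday 09:00 of week 1
        arr[hole] = np.nan
        values[:] = arr
        out = fill_phase_dependent(values)
        assert out.iloc[hole] == pytest.approx(truth.iloc[hole])

    def test_whole_day_matches_per_minute_medians(self):
        # brute-force per-(dow, minute) medians on a 28-day fixture
        rng = np.random.default_rng(1)
        grid = minute_grid(pd.Timestamp("2020-04-06"), 28)
        values = pd.Series(rng.uniform(1, 3, len(grid)), index=grid)
        arr = values.to_numpy().copy()
        arr[3 * 1440: 4 * 1440] = np.nan  # whole Thursday of week 1
        gapped = pd.Series(arr, index=grid)
        out = fill_phase_dependent(gapped)
        # oracle: median over the other Thursdays of the first 14-day half
        half = gapped.iloc[: 14 * 1440]
        for m in range(0, 1440, 97):
            obs = [half.iloc[d * 1440 + m] for d in range(14)
                   if half.index[d * 1440].dayofweek == 3
                   and not np.isnan(half.iloc[d * 1440 + m])]
            assert out.iloc[3 * 1440 + m] == pytest.approx(np.median(obs))

    def test_no_gaps_unchanged(self):
        values = _weekly_periodic(14)
        out = fill_phase_dependent(values)
        np.testing.assert_array_equal(out.to_numpy(), values.to_numpy())

    def test_zero_error_on_periodic_signal_where_median_fails(self):
        values = _weekly_periodic(28)
        truth = values.to_numpy().copy()
        arr = truth.copy()
        arr[8 * 1440: 10 * 1440] = np.nan  # two full days in week 2
        gapped = pd.Series(arr, index=values.index)
        phase = fill_phase_dependent(gapped).to_numpy()
        med = fill_global_median(gapped).to_numpy()
        hole = slice(8 * 1440, 10 * 1440)
        assert np.abs(phase[hole] - truth[hole]).sum() == pytest.approx(0, abs=1e-9)
        assert np.abs(med[hole] - truth[hole]).sum() > 0


class TestFillSeries:
    def test_all_methods_leave_no_missing(self, small_cohort):
        series, _, _ = small_cohort
        from actvar.synthetic import inject_missingness

        gapped, _ = inject_missingness(series[0], [(30, 4), (1440, 1)], seed=0)
        for method in ("phase_dependent", "linear", "global_median", "zero"):
            out = fill_with_method(gapped.met, method)
            assert out.notna().all()

    def test_observed_values_preserved(self, small_cohort):
        series, _, _ = small_cohort
        from actvar.synthetic import inject_missingness

        gapped, _ = inject_missingness(series[0], [(60, 3)], seed=1)
        obs = ~gapped.missing_mask
        filled = fill_series(gapped)
        np.testing.assert_array_equal(filled.met.to_numpy()[obs],
                                      gapped.met.to_numpy()[obs])
        assert not filled.missing_mask.any()

    def test_policy_routing(self):
        policy = FillPolicy.from_breakpoint(40)
        assert policy.method_for(5) == "linear"
        assert policy.method_for(40) == "linear"
        assert policy.method_for(41) == "phase_dependent"
        assert policy.method_for(9999) == "phase_dependent"


class TestEvaluateFillers:
    def test_constant_cohort_ties_broken_by_method_order(self):
        values = np.full(28 * 1440, 2.0)
        cohort = [make_series(values, participant_id=f"C{i}") for i in range(2)]
        evaluation, policy = evaluate_fillers(cohort, gap_grid=(5, 1440), seed=0)
        totals = evaluation.totals()
        nonzero = totals[totals["error"] > 0]["method"].unique()
        assert set(nonzero) <= {"zero"}
        assert set(policy.methods.values()) == {"phase_dependent"}

    def test_indeterminate_accounting(self):
        # a pre-existing hole under an injected gap is excluded and counted
        values = np.full(28 * 1440, 2.0)
        values[1000:3000] = np.nan
        cohort = [make_series(values)]
        evaluation, _ = evaluate_fillers(cohort, gap_grid=(1440,), seed=3)
        row = evaluation.table.iloc[0]
        assert row["n_test"] + row["indeterminate"] == 1440
        assert evaluation.indeterminate_fraction() >= 0

    def test_sleep_state_predictions_rounded(self):
        spec = CohortSpec(n_participants=2, days=28, seed=13, missingness=[])
        series, _, _ = generate_cohort(spec)
        evaluation, _ = evaluate_fillers(series, gap_grid=(5, 320), seed=5,
                                         kind="state")
        # absolute state errors are counts of wrong minutes -> integers
        errs = evaluation.table["error"].to_numpy()
        np.testing.assert_array_equal(errs, np.round(errs))
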