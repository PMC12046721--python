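import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lendingrisk as lr
from lendingrisk.trajectory import TRAJECTORY_LEVELS, classify_tracts


class TestDichotomizeHRS:
    def test_linear_interpolation_cutoff(self):
        # 25th percentile of [1,2,3,4] interpolates to 1.75
        flags = lr.dichotomize_hrs(np.array([1.0, 2.0, 3.0, 4.0]), 25)
        assert flags.tolist() == [0.0, 1.0, 1.0, 1.0]

    def test_all_equal_all_flagged(self):
        flags = lr.dichotomize_hrs(np.array([2.5, 2.5, 2.5]))
        assert flags.tolist() == [1.0, 1.0, 1.0]  # value >= its own cutoff

    def test_single_value(self):
        assert lr.dichotomize_hrs(np.array([4.0])).tolist() == [1.0]

    def test_missing_values_propagate(self):
        flags = lr.dichotomize_hrs(np.array([1.0, np.nan, 4.0]), 25)
        assert np.isnan(flags[1]) and flags[0] == 0.0 and flags[2] == 1.0

    @pytest.mark.parametrize("pct", [0.0, 100.0, -5.0])
    def test_bad_percentile(self, pct):
        with pytest.raises(ValueError, match="percentile"):
            lr.dichotomize_hrs(np.array([1.0, 2.0]), pct)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            lr.dichotomize_hrs(np.array([np.nan]))


class TestLendingFlags:
    def _twenty_tracts(self):
        # 20 tracts: loans 10..200 by 10; the 10th percentile is 29 (interpolated)
        loans = np.arange(10.0, 210.0, 10.0)
        frac = np.full(20, 0.05)
        return loans, frac

    def test_high_cost_alone_triggers(self):
        loans, frac = self._twenty_tracts()
        frac[15] = 0.20  # well above the loan-volume cutoff
        low, high, cur = lr.flag_lending_discrimination(loans, frac)
        assert (low[15], high[15], cur[15]) == (0.0, 1.0, 1.0)

    def test_below_both_thresholds(self):
        loans, frac = self._twenty_tracts()
        frac[15] = 0.10
        low, high, cur = lr.flag_lending_discrimination(loans, frac)
        assert (low[15], high[15], cur[15]) == (0.0, 0.0, 0.0)

    def test_threshold_boundary_inclusive(self):
        loans, frac = self._twenty_tracts()
        frac[12] = 0.15  # >= 15% counts as high-cost
        _, high, cur = lr.flag_lending_discrimination(loans, frac)
        assert high[12] == 1.0 and cur[12] == 1.0

    def test_zero_loan_tract_low_lending_arm(self):
        loans, frac = self._twenty_tracts()
        loans[0] = 0.0
        frac[0] = np.nan  # no originated loans: share undefined
        low, high, cur = lr.flag_lending_discrimination(loans, frac)
        assert low[0] == 1.0  # 0 is <= any 10th percentile of nonnegative data
        assert np.isnan(high[0])
        assert cur[0] == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            lr.flag_lending_discrimination(np.array([np.nan]), np.array([np.nan]))

    @given(thr=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=30, deadline=None)
    def test_raising_cost_threshold_is_monotone(self, thr):
        """No tract gains a discrimination flag when the threshold rises."""
        rng = np.random.default_rng(0)
        loans = rng.uniform(1, 100, 30)
        frac = rng.uniform(0, 1, 30)
        _, _, cur_lo = lr.flag_lending_discrimination(loans, frac, cost_threshold=thr)
        _, _, cur_hi = lr.flag_lending_discrimination(
            loans, frac, cost_threshold=min(thr + 0.2, 1.0)
        )
        assert np.all(cur_hi <= cur_lo)


class TestAssignTrajectory:
    @pytest.mark.parametrize(
        "historic, current, expected",
        [
            (False, False, "high_investment"),
            (True, False, "growing_investment"),
            (False, True, "disinvested"),
            (True, True, "sustained_disinvestment"),
        ],
    )
    def test_truth_table(self, historic, current, expected):
        assert lr.assign_trajectory(historic, current) == expected

    def test_exhaustive_and_exclusive(self):
        labels = {
            lr.assign_trajectory(h, c) for h in (False, True) for c in (False, True)
        }
        assert labels == set(TRAJECTORY_LEVELS)


class TestClassifyTracts:
    def test_missing_hrs_excluded_with_reason(self, small_study):
        _, table, _, _ = small_study
        table = table.copy()
        table.loc[0, "hrs"] = np.nan
        result = classify_tracts(table)
        assert result.exclusion_reasons.get("hrs_missing") == 1
        assert result.table.loc[0, "trajectory"] == ""
        included = result.table[result.table["exclusion_reason"] == ""]
        assert set(included["trajectory"]) <= set(TRAJECTORY_LEVELS)
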