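import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spabalance.preprocessing import MinuteGroup
from spabalance.spa_metrics import (
    DayProfile,
    MinuteRecord,
    auc_trapezoid,
    baseline_correct,
    daily_value,
    dispersion,
    extremes,
    minute_record,
    mwc,
    relative_auc,
    swc,
    weight_changes,
)


def group_from_cells(w1, w2, w3):
    w = np.column_stack([w1, w2, w3])
    return MinuteGroup(minute_stamp=0, t_us=np.arange(len(w)), w=w)


def day_from_mwc(values, day_id="day00"):
    records = [
        MinuteRecord(
            minute_stamp=660 + i, minute_of_day=660 + i, phase="dark",
            n_samples=2400, n_diffs=2399, swc=v * 2399, mwc=v,
            sd_wc=0.0, cv_wc=0.0,
        )
        for i, v in enumerate(values)
    ]
    return DayProfile(day_id=day_id, records=records)


class TestWeightChanges:
    def test_single_active_cell(self):
        g = group_from_cells([0, 1, 0, 1], [5, 5, 5, 5], [2, 2, 2, 2])
        np.testing.assert_allclose(weight_changes(g), [1, 1, 1])

    def test_redistribution_sensitivity_of_combine_modes(self):
        """Weight moving from one cell to another (ambulation) registers
        under per_cell_abs but cancels under resultant_first."""
        g = group_from_cells([0, 1], [1, 0], [3, 3])
        np.testing.assert_allclose(weight_changes(g, "per_cell_abs"), [2.0])
        np.testing.assert_allclose(weight_changes(g, "resultant_first"), [0.0])

    def test_constant_weights_give_zero_changes(self):
        g = group_from_cells([4, 4, 4], [4, 4, 4], [4, 4, 4])
        np.testing.assert_allclose(weight_changes(g), [0.0, 0.0])

    def test_short_minutes_give_empty_sequence(self):
        assert len(weight_changes(MinuteGroup(minute_stamp=0))) == 0
        assert len(weight_changes(group_from_cells([1], [1], [1]))) == 0

    def test_unknown_combine_rejected(self):
        with pytest.raises(ValueError, match="combine"):
            weight_changes(group_from_cells([1, 2], [1, 2], [1, 2]), "sum")

    def test_matches_elementwise_oracle(self, rng):
        w = rng.normal(200, 10, size=(100, 3))
        g = MinuteGroup(minute_stamp=0, t_us=np.arange(100), w=w)
        oracle = [
            sum(abs(w[i + 1, c] - w[i, c]) for c in range(3))
            for i in range(99)
        ]
        np.testing.assert_allclose(weight_changes(g), oracle)


class TestSwcMwc:
    def test_swc_sums(self):
        assert swc([1.0, 1.0, 1.0]) == pytest.approx(3.0)

    def test_mwc_means(self):
        assert mwc([2.0, 2.0, 2.0]) == pytest.approx(2.0)

    def test_empty_minute_is_zero(self):
        assert swc([]) == 0.0
        assert mwc([]) == 0.0

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_identity_swc_equals_mwc_times_n(self, changes):
        assert swc(changes) == pytest.approx(mwc(changes) * len(changes))

    @given(
        st.lists(st.floats(0, 1e3), min_size=1, max_size=50),
        st.integers(2, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_duplication_doubles_swc_keeps_mwc(self, changes, k):
        """A k-fold higher sampling count with the same per-step
        distribution scales SWC by k and leaves MWC unchanged — the
        reason MWC is robust to sampling-rate fluctuation."""
        dup = list(changes) * k
        assert swc(dup) == pytest.approx(k * swc(changes), rel=1e-9)
        assert mwc(dup) == pytest.approx(mwc(changes), rel=1e-9)


class TestDispersion:
    def test_constant_changes(self):
        sd, cv = dispersion([2.0, 2.0, 2.0, 2.0])
        assert sd == 0.0 and cv == 0.0

    def test_two_values_hand_computed(self):
        sd, cv = dispersion([1.0, 3.0])
        assert sd == pytest.approx(math.sqrt(2))
        assert cv == pytest.approx(100 * math.sqrt(2) / 2)

    def test_equal_mwc_different_cv(self):
        """Two minutes with identical MWC can have different CV-WC:
        steady motion vs a few large displacements."""
        steady = [2.0, 2.0, 2.0, 2.0]
        bursty = [0.0, 0.0, 0.0, 8.0]
        assert mwc(steady) == mwc(bursty) == pytest.approx(2.0)
        assert dispersion(bursty)[1] > dispersion(steady)[1]

    def test_zero_mean_cv_missing(self):
        sd, cv = dispersion([0.0, 0.0])
        assert sd == 0.0 and math.isnan(cv)

    def test_fewer_than_two_changes_undefined(self):
        sd, cv = dispersion([1.0])
        assert math.isnan(sd) and math.isnan(cv)


class TestMinuteRecord:
    def test_record_assembles_consistent_fields(self):
        g = group_from_cells([0, 1, 0], [0, 0, 0], [0, 0, 0])
        g.minute_stamp = 700
        r = minute_record(g)
        assert r.phase == "dark"
        assert r.n_samples == 3 and r.n_diffs == 2
        assert r.swc == pytest.approx(r.mwc * r.n_diffs)

    def test_empty_minute_yields_zero_statistics(self):
        r = minute_record(MinuteGroup(minute_stamp=661))
        assert r.swc == 0.0 and r.mwc == 0.0 and r.n_diffs == 0


class TestBaselineCorrect:
    def test_hand_computed_example(self):
        day = baseline_correct(day_from_mwc([5.0, 7.0, 9.0]))
        np.testing.assert_allclose(day.mwc_values(corrected=True), [0.0, 2.0, 4.0])
        assert day.baseline_bias == pytest.approx(5.0)

    def test_zero_minimum_day_unchanged(self):
        day = baseline_correct(day_from_mwc([0.0, 3.0]))
        assert day.baseline_bias == 0.0
        np.testing.assert_allclose(day.mwc_values(corrected=True), [0.0, 3.0])

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(DayProfile(day_id="x", records=[]))

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_minimum_zero_and_differences_preserved(self, values):
        day = baseline_correct(day_from_mwc(values))
        corrected = day.mwc_values(corrected=True)
        assert corrected.min() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(
            np.diff(corrected), np.diff(values), atol=1e-9
        )


class TestDailyValueAndExtremes:
    def test_constant_day(self):
        day = baseline_correct(day_from_mwc([3.0] * 5))
        assert daily_value(day) == pytest.approx(0.0)  # bias removed
        (nadir_m, nadir_v), (acro_m, acro_v) = extremes(day)
        assert nadir_m == acro_m == 660  # tie -> earliest minute

    def test_mean_of_minutes(self):
        day = baseline_correct(day_from_mwc([0.0, 2.0, 4.0]))
        assert daily_value(day) == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        values = rng.uniform(0, 50, size=30)
        a = baseline_correct(day_from_mwc(values))
        b = baseline_correct(day_from_mwc(rng.permutation(values)))
        assert daily_value(a) == pytest.approx(daily_value(b))

    def test_acrophase_at_crafted_maximum(self):
        values = [1.0] * 100
        values[37] = 50.0  # unique max 37 minutes after 11:00 -> 11:37
        day = baseline_correct(day_from_mwc(values))
        (_, nadir_v), (acro_m, acro_v) = extremes(day)
        assert acro_m == 660 + 37
        assert nadir_v == pytest.approx(0.0)  # corrected day nadir is 0

    def test_uncorrected_day_rejected(self):
        with pytest.raises(ValueError, match="corrected"):
            daily_value(day_from_mwc([1.0, 2.0]))


class TestAuc:
    def test_two_point_hand_value(self):
        assert auc_trapezoid([1.0, 3.0]) == pytest.approx(2.0)

    def test_constant_closed_form(self):
        assert auc_trapezoid([5.0] * 23) == pytest.approx(22 * 5.0)

    def test_agrees_with_fine_grid_oracle(self, rng):
        values = rng.uniform(0, 100, size=23)
        fine_x = np.linspace(0, 22, 22_001)
        fine_y = np.interp(fine_x, np.arange(23), values)
        oracle = np.trapezoid(fine_y, fine_x)
        assert auc_trapezoid(values) == pytest.approx(oracle, rel=1e-6)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([1.0])

    def test_relative_auc(self):
        assert relative_auc(112.0, 100.0) == pytest.approx(112.0)
        assert relative_auc(5.0, 5.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            relative_auc(1.0, 0.0)
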