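"""Volume conversion, cohort aggregation, FTGR, and TGI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftgr import (
    CaliperRecord,
    GridError,
    InvalidMeasurementError,
    VolumeSeries,
    animal_series,
    compute_ftgr,
    compute_tgi,
    compute_volume,
    group_mean_series,
    interval_growth_rate,
)
from conftest import exp_series


class TestComputeVolume:
    @pytest.mark.parametrize(
        "width,length,expected",
        [(4.0, 7.5, 60.0), (2.0, 2.0, 4.0), (3.0, 8.0, 36.0)],
    )
    def test_ellipsoid_formula(self, width, length, expected):
        assert compute_volume(width, length) == pytest.approx(expected)

    @pytest.mark.parametrize("width,length", [(0.0, 5.0), (-1.0, 5.0), (3.0, 0.0)])
    def test_rejects_non_positive_dimensions(self, width, length):
        with pytest.raises(InvalidMeasurementError):
            compute_volume(width, length)


class TestCaliperRecord:
    def test_transposed_dimensions_swap_with_warning(self):
        with pytest.warns(UserWarning, match="swap"):
            rec = CaliperRecord("a1", "g", 0, width=7.5, length=4.0)
        assert (rec.width, rec.length) == (4.0, 7.5)
        assert rec.volume == pytest.approx(60.0)


class TestGroupMeanSeries:
    def _records(self, volumes_by_animal):
        recs = []
        for animal, per_day in volumes_by_animal.items():
            for day, v in per_day.items():
                length = (2 * v) ** (1 / 3)  # width == length cube
                recs.append(CaliperRecord(animal, "g", day, length, length))
        return recs

    def test_two_point_mean(self):
        recs = self._records({"a1": {0: 60.0}, "a2": {0: 80.0}})
        series = group_mean_series(recs, "g")
        assert series.volumes[0] == pytest.approx(70.0)
        assert series.n_animals[0] == 2

    def test_dead_animal_drops_out_and_count_shrinks(self):
        recs = self._records(
            {"a1": {0: 60.0, 2: 80.0, 4: 100.0}, "a2": {0: 60.0, 2: 90.0}}
        )
        series = group_mean_series(recs, "g")
        assert series.n_animals.tolist() == [2, 2, 1]
        assert series.volumes[2] == pytest.approx(100.0)

    def test_interior_gap_is_hard_error_by_default(self):
        recs = self._records({"a1": {0: 60.0, 4: 100.0}, "a2": {0: 60.0, 2: 80.0, 4: 90.0}})
        with pytest.raises(GridError, match="missing days"):
            group_mean_series(recs, "g")

    def test_gap_repair_interpolates_in_log_volume(self):
        recs = self._records({"a1": {0: 100.0, 4: 400.0},
                              "a2": {0: 100.0, 2: 200.0, 4: 400.0}})
        series = group_mean_series(recs, "g", gap_policy="interpolate")
        # geometric midpoint of 100 and 400 is 200
        assert series.value_at(2) == pytest.approx(200.0, rel=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="no alive records"):
            group_mean_series([], "g")

    def test_animal_series_diagnostic(self):
        recs = self._records({"a1": {0: 60.0, 2: 80.0}})
        series = animal_series(recs, "a1")
        assert series.volumes == pytest.approx([60.0, 80.0])


class TestVolumeSeries:
    def test_non_uniform_grid_rejected(self):
        with pytest.raises(GridError):
            VolumeSeries("g", [0, 2, 6], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_non_positive_volume_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            VolumeSeries("g", [0, 2], [1.0, 0.0], [1, 1])


class TestFTGR:
    def test_worked_triplet(self, worked_series):
        trace = compute_ftgr(worked_series, "latest")
        assert trace.days.tolist() == [4, 6]
        assert trace.values == pytest.approx([-125.0 / 6, 125.0 / 6], abs=5e-3)
        assert trace.values[0] == pytest.approx(12.5 - 100 / 3)

    def test_middle_convention_shifts_labels_by_one_step(self, worked_series):
        latest = compute_ftgr(worked_series, "latest")
        middle = compute_ftgr(worked_series, "middle")
        h = worked_series.step
        assert (latest.days - h).tolist() == middle.days.tolist()
        np.testing.assert_allclose(latest.values, middle.values)

    def test_exponential_series_gives_zero(self):
        series = exp_series(60.0, 0.25, np.arange(0, 21, 2))
        trace = compute_ftgr(series)
        growth = 100 * (np.exp(0.25 * 2) - 1)
        np.testing.assert_allclose(trace.values, 0.0, atol=growth * 1e-9)

    def test_constant_series_gives_zero(self):
        series = VolumeSeries("g", [0, 2, 4, 6], [80.0] * 4, [6] * 4)
        np.testing.assert_allclose(compute_ftgr(series).values, 0.0, atol=1e-12)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(GridError):
            compute_ftgr(VolumeSeries("g", [0, 2], [60.0, 80.0], [6, 6]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        volumes=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=12),
        scale=st.floats(0.01, 100.0),
    )
    def test_matches_brute_force_and_is_scale_invariant(self, volumes, scale):
        """compute_ftgr equals a direct per-triplet evaluation of the
        definition, and rescaling all volumes leaves it unchanged."""
        v = np.array(volumes)
        days = np.arange(len(v)) * 2
        series = VolumeSeries("g", days, v, np.ones(len(v), dtype=int))
        trace = compute_ftgr(series, "latest")
        brute = [
            100 * (v[i + 1] - v[i]) / v[i] - 100 * (v[i] - v[i - 1]) / v[i - 1]
            for i in range(1, len(v) - 1)
        ]
        np.testing.assert_allclose(trace.values, brute, rtol=1e-12)
        scaled = compute_ftgr(
            VolumeSeries("g", days, scale * v, np.ones(len(v), dtype=int)), "latest"
        )
        np.testing.assert_allclose(scaled.values, trace.values, rtol=1e-9, atol=1e-9)

    def test_causality_of_latest_labels(self, worked_series):
        """Changing a future volume must not change earlier-labelled values."""
        trace = compute_ftgr(worked_series, "latest")
        bumped = VolumeSeries("g", worked_series.days,
                              worked_series.volumes * np.array([1, 1, 1, 2.0]),
                              worked_series.n_animals)
        bumped_trace = compute_ftgr(bumped, "latest")
        assert bumped_trace.value_at(4) == pytest.approx(trace.value_at(4))
        assert bumped_trace.value_at(6) != pytest.approx(trace.value_at(6))


class TestIntervalGrowthRate:
    def test_examples(self, worked_series):
        assert interval_growth_rate(worked_series, 2) == pytest.approx(100 / 3)
        const = VolumeSeries("g", [0, 2, 4], [50.0] * 3, [6] * 3)
        assert interval_growth_rate(const, 4) == pytest.approx(0.0)

    def test_exponential_closed_form(self):
        series = exp_series(60.0, 0.2, np.arange(0, 11, 2))
        expected = 100 * (np.exp(0.2 * 2) - 1)
        for day in series.days[1:]:
            assert interval_growth_rate(series, int(day)) == pytest.approx(expected)

    def test_day_off_grid_rejected(self, worked_series):
        with pytest.raises(GridError):
            interval_growth_rate(worked_series, 3)


class TestTGI:
    def test_fold_change_2_vs_10_gives_80_percent(self):
        treated = VolumeSeries("t", [0, 20], [62.0, 124.0], [6, 6])
        control = VolumeSeries("c", [0, 20], [58.0, 580.0], [6, 6])
        assert compute_tgi(treated, control, 20).tgi == pytest.approx(80.0)

    def test_equal_fold_changes_give_zero(self):
        treated = VolumeSeries("t", [0, 10], [50.0, 200.0], [6, 6])
        control = VolumeSeries("c", [0, 10], [80.0, 320.0], [6, 6])
        assert compute_tgi(treated, control, 10).tgi == pytest.approx(0.0)

    def test_vanishing_treated_volume_approaches_100(self):
        control = VolumeSeries("c", [0, 10], [60.0, 600.0], [6, 6])
        treated = VolumeSeries("t", [0, 10], [60.0, 1e-9], [6, 6])
        assert compute_tgi(treated, control, 10).tgi == pytest.approx(100.0, abs=1e-6)

    def test_unit_invariance_per_arm(self):
        treated = VolumeSeries("t", [0, 10], [60.0, 240.0], [6, 6])
        control = VolumeSeries("c", [0, 10], [60.0, 600.0], [6, 6])
        ref = compute_tgi(treated, control, 10).tgi
        treated2 = VolumeSeries("t", [0, 10], [6.0, 24.0], [6, 6])
        control2 = VolumeSeries("c", [0, 10], [600.0, 6000.0], [6, 6])
        assert compute_tgi(treated2, control2, 10).tgi == pytest.approx(ref)

    def test_missing_eval_day_rejected(self):
        series = VolumeSeries("t", [0, 10], [60.0, 240.0], [6, 6])
        with pytest.raises(GridError):
            compute_tgi(series, series, 5)
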