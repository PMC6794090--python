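"""Monitor-file parsing, binning and day-window slicing."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyclock import dam
from flyclock.dam import (
    ActivitySeries,
    CohortTable,
    DamFormatError,
    LightSchedule,
    bin_series,
    default_schedule,
    read_dam_monitor,
    slice_window,
    write_dam_monitor,
)


def _minute_series(counts, schedule, fly_id="f0"):
    return ActivitySeries.from_counts(
        fly_id, schedule.ld_start(), 1, np.asarray(counts), schedule
    )


class TestMonitorIO:
    def test_two_channels_of_ones(self, tmp_path, schedule):
        series = [
            _minute_series(np.ones(60, dtype=int), schedule, f"f{i}") for i in range(2)
        ]
        path = write_dam_monitor(series, tmp_path / "Monitor1.txt")
        back = read_dam_monitor(path, schedule)
        assert len(back) == 2
        for s in back:
            assert len(s) == 60
            assert s.counts.sum() == 60

    def test_zero_series_writes_rows(self, tmp_path, schedule):
        s = _minute_series(np.zeros(10, dtype=int), schedule)
        path = write_dam_monitor([s], tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        assert len(lines) == 10
        assert all(line.split("\t")[10] == "0" for line in lines)

    def test_malformed_row_names_line(self, tmp_path, schedule):
        s = _minute_series(np.ones(20, dtype=int), schedule)
        path = write_dam_monitor([s], tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        lines[12] = "\t".join(lines[12].split("\t")[:-1])  # drop a count column
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DamFormatError, match="line 13"):
            read_dam_monitor(path, schedule)

    def test_non_monotonic_timestamps_rejected(self, tmp_path, schedule):
        s = _minute_series(np.ones(5, dtype=int), schedule)
        path = write_dam_monitor([s], tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        lines[3] = lines[1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DamFormatError, match="monotonic"):
            read_dam_monitor(path, schedule)

    def test_too_many_channels(self, tmp_path, schedule):
        series = [
            _minute_series(np.ones(5, dtype=int), schedule, f"f{i}") for i in range(33)
        ]
        with pytest.raises(ValueError, match="32"):
            write_dam_monitor(series, tmp_path / "m.txt")

    def test_invalid_status_rows_flagged_and_zeroed(self, tmp_path, schedule):
        s = _minute_series(np.full(8, 3), schedule)
        path = write_dam_monitor([s], tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        fields = lines[4].split("\t")
        fields[3] = "51"
        lines[4] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        (back,) = read_dam_monitor(path, schedule)
        assert back.counts[4] == 0 and back.flagged[4]
        assert back.counts.sum() == 7 * 3
        assert len(back) == 8  # flagged, not dropped: spacing stays regular

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_identity(self, tmp_path_factory, seed):
        """write -> read recovers counts and timestamps exactly."""
        schedule = default_schedule(n_ld_days=1)
        rng = np.random.default_rng(seed)
        n_ch = int(rng.integers(1, 5))
        counts = rng.poisson(1.0, size=(n_ch, 120))
        counts[:, 0] += 1  # keep every channel non-empty
        series = [
            _minute_series(counts[i], schedule, f"f{i}") for i in range(n_ch)
        ]
        path = tmp_path_factory.mktemp("dam") / "Monitor.txt"
        write_dam_monitor(series, path)
        back = read_dam_monitor(path, schedule)
        assert len(back) == n_ch
        for orig, rec in zip(series, back):
            np.testing.assert_array_equal(orig.counts, rec.counts)
            assert rec.t0 == orig.t0


class TestBinning:
    def test_sixty_ones_to_four_quarters(self, schedule):
        s = _minute_series(np.ones(60, dtype=int), schedule)
        b = bin_series(s, 15)
        np.testing.assert_array_equal(b.counts, [15, 15, 15, 15])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_and_associativity(self, seed):
        schedule = default_schedule(n_ld_days=0)
        rng = np.random.default_rng(seed)
        s = _minute_series(rng.poisson(2.0, size=2 * 1440), schedule)
        b15 = bin_series(s, 15)
        assert b15.counts.sum() == s.counts.sum()
        b60_via_15 = bin_series(b15, 60)
        b60_direct = bin_series(s, 60)
        np.testing.assert_array_equal(b60_via_15.counts, b60_direct.counts)

    def test_non_divisible_width_rejected(self, schedule):
        s = _minute_series(np.ones(120, dtype=int), schedule)
        with pytest.raises(ValueError):
            bin_series(s, 7)
        with pytest.raises(ValueError):
            bin_series(bin_series(s, 15), 40)

    def test_phase_labels_periodic(self, schedule):
        s = _minute_series(np.ones(3 * 1440, dtype=int), schedule)
        for width in (15, 60):
            b = bin_series(s, width)
            per_day = 1440 // width
            np.testing.assert_allclose(b.phase[:per_day], b.phase[per_day : 2 * per_day])


class TestSliceWindow:
    def test_dd_day_two(self, dd_schedule):
        s = _minute_series(np.ones(10 * 1440, dtype=int), dd_schedule)
        w = slice_window(bin_series(s, 60), "DD", 2, 1)
        assert len(w) == 24
        assert w.phase[0] == 0.0
        assert w.t0 == dd_schedule.dd_start + timedelta(days=1)

    def test_window_beyond_record(self, dd_schedule):
        s = _minute_series(np.ones(10 * 1440, dtype=int), dd_schedule)
        with pytest.raises(ValueError, match="10"):
            slice_window(bin_series(s, 60), "DD", 12, 1)

    def test_day_slices_partition_full_window(self, dd_schedule):
        rng = np.random.default_rng(5)
        s = bin_series(
            _minute_series(rng.poisson(1.0, 6 * 1440), dd_schedule), 30
        )
        full = slice_window(s, "DD", 1, 6)
        parts = [slice_window(s, "DD", d, 1).counts for d in range(1, 7)]
        np.testing.assert_array_equal(np.concatenate(parts), full.counts)

    def test_ld_and_dd_regimes_labeled(self, schedule):
        s = _minute_series(np.ones(4 * 1440, dtype=int), schedule)
        assert set(s.regime[: 2 * 1440]) == {"LD"}
        assert set(s.regime[2 * 1440 :]) == {"DD"}


class TestTypes:
    def test_light_schedule_invariants(self):
        with pytest.raises(ValueError):
            LightSchedule(8, 8, 2, datetime(2024, 1, 3, 8))
        sched = default_schedule()
        assert sched.photoperiod_h == 12.0

    def test_cohort_rejects_duplicate_ids(self, make_series):
        a = make_series(np.ones(4, dtype=int), fly_id="x")
        b = make_series(np.ones(4, dtype=int), fly_id="x")
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable({"g1": [a], "g2": [b]})
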