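"""Detector/logger model: pulse extension, logging cycle, CSV format."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_log
from dopplercage.device import (
    CageArray,
    CsvFormatError,
    EventLog,
    activity_per_minute,
    extend_pulses,
    log_events,
    read_csv,
    write_csv,
)
from dopplercage.synthetic import ActivityTrace, simulate_homogeneous


class TestExtendPulses:
    @pytest.mark.parametrize(
        "events, expected",
        [
            ([0.0], [(0.0, 1.0)]),
            ([0.0, 0.4, 0.9], [(0.0, 1.9)]),
            ([0.0, 2.5], [(0.0, 1.0), (2.5, 3.5)]),
        ],
    )
    def test_retrigger_semantics(self, events, expected):
        assert extend_pulses(events) == expected

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            extend_pulses([1.0, 0.5])

    @given(st.lists(st.floats(0, 1e5, allow_nan=False), min_size=1, max_size=50),
           st.floats(0.1, 5.0))
    def test_high_time_bounds_and_disjointness(self, events, hold):
        events = sorted(events)
        pulses = extend_pulses(events, hold)
        total = sum(b - a for a, b in pulses)
        assert hold - 1e-9 <= total <= len(events) * hold + 1e-9
        for (a1, b1), (a2, b2) in zip(pulses, pulses[1:]):
            assert b1 <= a2


def _single_cage(times, channel=2):
    trace = ActivityTrace("t", np.asarray(times, dtype=float), None, 0)
    return CageArray(occupancy={channel: trace})


class TestLogEvents:
    def test_one_record_per_spaced_event(self):
        log = log_events(_single_cage([1.0, 2.0, 3.0, 4.0]), seed=0)
        assert len(log) == 4
        assert log.flag_count(2) == 4

    def test_only_occupied_channel_flagged(self):
        log = log_events(_single_cage(np.arange(1, 60, 2.0)), seed=0)
        for ch in (1, 3, 4, 5, 6):
            assert log.flag_count(ch) == 0

    def test_timestamps_floored_to_seconds(self):
        log = log_events(_single_cage([1.7, 9.2]), seed=0, start="2024-01-01")
        assert list(log.frame["datetime"]) == [
            pd.Timestamp("2024-01-01 00:00:01"),
            pd.Timestamp("2024-01-01 00:00:09"),
        ]

    def test_dead_time_absorbs_bursts(self):
        # events 0.05 s apart with dead_time 0.2: only some trigger records
        log = log_events(_single_cage(np.arange(1.0, 2.0, 0.05)), seed=0,
                         dead_time=0.2)
        assert len(log) < 20

    def test_shielded_neighbor_silent_over_30_min(self):
        trace = simulate_homogeneous(0.5, (0.0, 1800.0), 4, "cage2")
        xt = np.eye(6)
        xt[0, 1] = 0.26
        xt[2, 1] = 0.26
        cages = CageArray(occupancy={2: trace}, crosstalk=xt,
                          shields=frozenset({frozenset({2, 3})}))
        log = log_events(cages, seed=5)
        assert log.flag_count(3) == 0
        assert log.flag_count(1) > 0

    def test_crosstalk_fraction_recovery(self):
        p = 0.26
        trace = simulate_homogeneous(0.2, (0.0, 3600.0), 8, "cage2")
        xt = np.eye(6)
        xt[0, 1] = p
        cages = CageArray(occupancy={2: trace}, crosstalk=xt)
        log = log_events(cages, seed=9)
        n = log.flag_count(2)
        frac = log.flag_count(1) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_no_more_records_than_events(self):
        trace = simulate_homogeneous(2.0, (0.0, 600.0), 3, "cage1")
        cages = CageArray(occupancy={1: trace})
        log = log_events(cages, seed=1)
        assert len(log) <= len(trace)

    def test_empty_cages_rejected(self):
        with pytest.raises(ValueError):
            log_events(CageArray(occupancy={}), seed=0)

    def test_crosstalk_matrix_validation(self):
        bad = np.eye(6)
        bad[0, 0] = 0.5
        with pytest.raises(ValueError):
            CageArray(occupancy={}, crosstalk=bad)


class TestCsvRoundTrip:
    def test_empty_log_is_header_only(self, tmp_path):
        log = EventLog(pd.DataFrame(columns=["datetime", *[f"ch{i}" for i in range(1, 7)], "light"]))
        path = tmp_path / "empty.csv"
        write_csv(log, path)
        assert path.read_text().strip() == "datetime,ch1,ch2,ch3,ch4,ch5,ch6,light"

    def test_three_records_round_trip(self, tmp_path):
        log = make_log({1: [0, 2], 3: [5]}, light=512)
        path = tmp_path / "log.csv"
        write_csv(log, path)
        assert len(path.read_text().strip().splitlines()) == 4
        back = read_csv(path)
        pd.testing.assert_frame_equal(back.frame, log.frame)

    def test_flagless_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "datetime,ch1,ch2,ch3,ch4,ch5,ch6,light\n"
            "2024-01-01 00:00:00,1,0,0,0,0,0,10\n"
            "2024-01-01 00:00:05,0,0,0,0,0,0,10\n"
        )
        with pytest.raises(CsvFormatError, match="line 3"):
            read_csv(path)

    def test_non_monotone_rows_warn_and_sort(self, tmp_path):
        path = tmp_path / "swap.csv"
        path.write_text(
            "datetime,ch1,ch2,ch3,ch4,ch5,ch6,light\n"
            "2024-01-01 00:00:09,1,0,0,0,0,0,10\n"
            "2024-01-01 00:00:01,0,1,0,0,0,0,10\n"
        )
        with pytest.warns(UserWarning, match="re-sorting"):
            log = read_csv(path)
        assert log.frame["datetime"].is_monotonic_increasing

    def test_out_of_range_light_rejected(self, tmp_path):
        path = tmp_path / "light.csv"
        path.write_text(
            "datetime,ch1,ch2,ch3,ch4,ch5,ch6,light\n"
            "2024-01-01 00:00:00,1,0,0,0,0,0,2000\n"
        )
        with pytest.raises(CsvFormatError, match="line 2"):
            read_csv(path)


class TestActivityPerMinute:
    def test_sixty_records_in_one_minute(self):
        log = make_log({1: list(range(60))})
        counts = activity_per_minute(log, 1)
        assert list(counts) == [60]

    def test_empty_log_over_five_minutes(self):
        log = EventLog(pd.DataFrame(columns=["datetime", *[f"ch{i}" for i in range(1, 7)], "light"]))
        counts = activity_per_minute(
            log, 1, span=(pd.Timestamp("2024-01-01"), pd.Timestamp("2024-01-01 00:05:00"))
        )
        assert list(counts) == [0, 0, 0, 0, 0]

    def test_counts_conserve_flags(self):
        log = make_log({2: [0, 30, 61, 200, 400]})
        counts = activity_per_minute(log, 2)
        assert counts.sum() == log.flag_count(2)

    def test_unknown_channel_rejected(self):
        log = make_log({1: [0]})
        with pytest.raises(ValueError):
            activity_per_minute(log, 9)
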