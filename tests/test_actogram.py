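"""Actogram binning, group statistics, modulation and phase-shift recovery."""

import numpy as np
import pytest

from conftest import make_log
from dopplercage.actogram import (
    BinnedActivity,
    bin_activity,
    daily_profile,
    daily_totals,
    estimate_phase_shift,
    group_actogram,
    modulation,
    window_activity,
)
from dopplercage.lightcycle import DAY, HOUR, LightSchedule
from dopplercage.presets import child_seeds, circadian_shift, default_shift_schedule
from dopplercage.synthetic import CD1_LIKE, LAB_LIKE, ActivityTrace, simulate_mouse


def binned_from(counts, bin_width=HOUR, animal_id="a"):
    return BinnedActivity(animal_id, bin_width, np.asarray(counts))


class TestBinActivity:
    def test_counts_fall_in_hour_bins(self):
        log = make_log({1: [10 * 60, 20 * 60, 65 * 60]})
        b = bin_activity(log, 1)
        assert list(b.counts[:3]) == [2, 1, 0]

    def test_empty_channel_is_all_zero(self):
        log = make_log({2: [100]})
        b = bin_activity(log, 1, n_days=1)
        assert b.counts.sum() == 0 and b.counts.size == 24

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 2 * DAY, 500))
        trace = ActivityTrace("x", np.unique(times), None, 0)
        b = bin_activity(trace, bin_width=HOUR)
        assert b.counts.sum() == len(trace)

    def test_bin_width_must_tile_day(self):
        log = make_log({1: [0]})
        with pytest.raises(ValueError):
            bin_activity(log, 1, bin_width=7 * HOUR)


class TestGroupActogram:
    def test_single_animal_sem_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single animal"):
            g = group_actogram([binned_from(np.arange(24))])
        assert (g.sem == 0).all()
        np.testing.assert_array_equal(g.mean.ravel(), np.arange(24))

    def test_identical_animals_sem_zero(self):
        g = group_actogram([binned_from(np.ones(24)), binned_from(np.ones(24))])
        assert (g.sem == 0).all()

    def test_two_animal_sem(self):
        a = binned_from(np.zeros(24))
        b = binned_from(np.full(24, 2))
        g = group_actogram([a, b])
        assert g.mean[0, 0] == 1.0
        assert g.sem[0, 0] == pytest.approx(1.0)  # sd=sqrt(2), sem=sqrt(2)/sqrt(2)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            group_actogram([binned_from(np.zeros(24)), binned_from(np.zeros(48))])

    def test_sem_shrinks_as_inverse_sqrt_n(self):
        sched = LightSchedule()
        span = (0.0, 2 * DAY)
        seeds = child_seeds(99, 16)
        binned = [
            bin_activity(simulate_mouse(CD1_LIKE, sched, span, s), n_days=2)
            for s in seeds
        ]
        sem4 = group_actogram(binned[:4]).sem.mean()
        sem16 = group_actogram(binned).sem.mean()
        assert sem4 / sem16 == pytest.approx(2.0, rel=0.35)


class TestDailyTotals:
    def test_uniform_rate(self):
        b = binned_from(np.full(48, 10))
        np.testing.assert_array_equal(daily_totals(b), [240, 240])

    def test_partial_day_excluded_with_warning(self):
        b = binned_from(np.full(30, 1))
        with pytest.warns(UserWarning, match="partial"):
            totals = daily_totals(b)
        np.testing.assert_array_equal(totals, [24])

    def test_lab_doubles_cd1(self):
        result = circadian_shift(7)
        ratio = result["summary"]["lab_over_cd1_daily_activity"]
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestWindowActivity:
    def test_uniform_window(self):
        b = binned_from(np.full(24, 10))
        np.testing.assert_array_equal(window_activity(b, (14, 20)), [60])

    def test_windows_partition_day(self):
        rng = np.random.default_rng(1)
        b = binned_from(rng.integers(0, 50, 24 * 3))
        total = daily_totals(b)
        parts = sum(
            window_activity(b, w)
            for w in [(2, 8), (8, 14), (14, 20), (0, 2)]
        ) + window_activity(b, (20, 24))
        np.testing.assert_array_equal(parts, total)

    def test_unaligned_window_rejected(self):
        b = binned_from(np.zeros(24))
        with pytest.raises(ValueError):
            window_activity(b, (2.5, 8.0))

    def test_cd1_light_window_activity_collapses_after_shift(self):
        # window C (2 PM - 8 PM) is dark before the shift, light after; an
        # entraining animal's activity there must fall off over days 4-6
        sched = default_shift_schedule()
        b = bin_activity(
            simulate_mouse(CD1_LIKE, sched, (0.0, 6 * DAY), seed=21), n_days=6
        )
        c = window_activity(b, (14, 20))
        baseline = c[:2].mean()
        assert c[3] > c[4] > c[5]
        assert c[5] < 0.15 * baseline


class TestModulation:
    def test_stationary_activity_near_100(self):
        sched = LightSchedule()
        rng = np.random.default_rng(3)
        times = np.unique(np.sort(rng.uniform(0, 2 * DAY, 20000)))
        trace = ActivityTrace("h", times, sched, 0)
        table = modulation(trace, sched)
        assert len(table) == 4
        assert np.allclose(table["modulation_pct"], 100.0, atol=10.0)

    def test_rate_doubling_at_transition(self):
        # counts: 10/bin before the 8 AM dark onset, 20/bin after
        counts = np.concatenate([np.full(8, 10), np.full(16, 20)])
        b = binned_from(counts)
        table = modulation(b, LightSchedule(), span=(0.0, DAY))
        row = table[table["time"] == 8 * HOUR].iloc[0]
        assert row["modulation_pct"] == pytest.approx(200.0)

    def test_zero_pre_window_is_undefined_not_error(self):
        counts = np.concatenate([np.zeros(8), np.full(16, 5)])
        table = modulation(binned_from(counts), LightSchedule(), span=(0.0, DAY))
        row = table[table["time"] == 8 * HOUR].iloc[0]
        assert np.isnan(row["modulation_pct"])

    def test_lab_shows_no_modulation_at_new_dark_onset(self):
        # the non-entraining strain's internal phase ignores the shift, so
        # activity around the new 2 AM dark onsets stays flat (~100%)
        sched = default_shift_schedule()
        vals = []
        for s in child_seeds(31, 20):
            b = bin_activity(
                simulate_mouse(LAB_LIKE, sched, (0.0, 6 * DAY), s), n_days=6
            )
            table = modulation(b, sched)
            onsets = table[
                (table["direction"] == "LIGHT->DARK") & (table["time"] >= 3 * DAY)
            ]
            vals.extend(onsets["modulation_pct"].tolist())
        assert 80.0 <= float(np.median(vals)) <= 125.0


class TestPhaseShift:
    def test_identical_profiles(self, rng):
        p = rng.uniform(0, 10, 24)
        assert estimate_phase_shift(p, p) == 0.0

    @pytest.mark.parametrize("k", range(24))
    def test_all_rotations_recovered(self, k, rng):
        p = np.random.default_rng(8).uniform(0, 10, 24)
        expected = k if k <= 12 else k - 24
        assert estimate_phase_shift(p, np.roll(p, k)) == float(expected)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            estimate_phase_shift(np.ones(24), np.arange(24.0))

    def test_cd1_recovers_minus_6h_in_90pct_of_seeds(self):
        sched = default_shift_schedule()
        hits = 0
        seeds = child_seeds(77, 20)
        for s in seeds:
            b = bin_activity(
                simulate_mouse(CD1_LIKE, sched, (0.0, 6 * DAY), s), n_days=6
            )
            pre = daily_profile(b, [0, 1])
            post = daily_profile(b, [4, 5])
            if estimate_phase_shift(pre, post) == -6.0:
                hits += 1
        assert hits >= 18  # >= 90% of 20 seeds

    def test_advance_is_negative_sign_convention(self):
        sched = default_shift_schedule()
        b = bin_activity(
            simulate_mouse(CD1_LIKE, sched, (0.0, 6 * DAY), 5), n_days=6
        )
        shift = estimate_phase_shift(daily_profile(b, [0, 1]), daily_profile(b, [4, 5]))
        assert shift == -6.0
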