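"""Canned experiment presets.

Each preset wires simulate → log → analyze for one of the three bench/animal
experiments the pipeline reproduces, and returns a plain dict of artifacts
(traces, logs, tables, summary numbers).  The CLI's ``run-preset`` writes
these to disk; tests and the acceptance machinery call them directly.
"""

from __future__ import annotations

import numpy as np

from . import actogram as acto
from . import device
from .intervals import dominant_period, fraction_in_range, intervals, summarize
from .lightcycle import DAY, HOUR, LightSchedule
from .synthetic import (
    CD1_LIKE,
    LAB_LIKE,
    ClockSimSpec,
    StrainProfile,
    simulate_clock,
    simulate_homogeneous,
    simulate_mouse,
)

#: Crosstalk pickup observed between unshielded neighboring cages.
CROSSTALK_PICKUP = 0.26


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def clock_validation(
    seed: int,
    spec: ClockSimSpec | None = None,
    range_ms: tuple[float, float] = (0.950, 1.050),
) -> dict:
    """The analog-clock benchmark: 30 min of nominal 1 s ticks with jitter,
    missed detections and a 1-min interval modulation, then the full interval
    analysis (summary, fraction in range, dominant period)."""
    if spec is None:
        spec = ClockSimSpec(
            duration=1800.0,
            tick_interval=1.0,
            timestamp_jitter_sd=0.005,
            miss_probability=0.02,
            modulation_period=60.0,
            modulation_amplitude=0.010,
        )
    trace = simulate_clock(spec, seed)
    series = intervals(trace)
    summary = summarize(series)
    period = dominant_period(series)
    return {
        "trace": trace,
        "series": series,
        "summary": {
            "n_events": summary.n_events,
            "mean_s": summary.mean,
            "median_s": round(summary.median, 3),
            "percentiles_s": summary.percentiles,
            "fraction_in_range": fraction_in_range(series, *range_ms),
            "range_s": list(range_ms),
            "dominant_period_s": period,
        },
    }


def crosstalk_shielding(
    seed: int,
    pickup: float = CROSSTALK_PICKUP,
    rate: float = 0.5,
    duration: float = 1800.0,
) -> dict:
    """Three neighboring cages, only cage 2 occupied; cage 1 unshielded
    (pickup probability per event), cage 3 behind an aluminum-foil shield
    (pickup forced to 0).  Reports the recovered pickup percentage and the
    shielded channel's flag count."""
    s_trace, s_log = child_seeds(seed, 2)
    trace = simulate_homogeneous(rate, (0.0, duration), s_trace, "cage2")
    xtalk = np.eye(device.N_CHANNELS)
    xtalk[0, 1] = pickup  # cage-1 detector hears cage 2
    xtalk[2, 1] = pickup  # cage-3 would too, but the foil blocks it
    cages = device.CageArray(
        occupancy={2: trace}, crosstalk=xtalk, shields=frozenset({frozenset({2, 3})})
    )
    log = device.log_events(cages, seed=s_log)
    n2 = log.flag_count(2)
    n1 = log.flag_count(1)
    n3 = log.flag_count(3)
    return {
        "trace": trace,
        "log": log,
        "summary": {
            "occupied_flags": n2,
            "unshielded_neighbor_flags": n1,
            "shielded_neighbor_flags": n3,
            "pickup_pct": 100.0 * n1 / n2 if n2 else float("nan"),
        },
    }


def default_shift_schedule() -> LightSchedule:
    """Inverted 12/12 cycle (ON 8 PM, OFF 8 AM) with the −6 h advance on
    day 3, applied by shortening that day's dark period."""
    return LightSchedule(light_on_at=20.0, light_off_at=8.0).shifted_on_day(3, -6.0)


def circadian_shift(
    seed: int,
    n_cd1: int = 4,
    n_lab: int = 3,
    days: int = 6,
    cd1: StrainProfile = CD1_LIKE,
    lab: StrainProfile = LAB_LIKE,
    schedule: LightSchedule | None = None,
) -> dict:
    """The two-strain light-cycle-shift experiment.

    Simulates n_cd1 CD1-like and n_lab LAB-like animals for ``days`` days
    under the shifted schedule, bins at 1 h, and computes group actograms,
    daily totals, the A/B/C window tables, the light-transition modulation
    table, and the recovered phase shift (baseline days 1–2 vs days 5–6).
    """
    if schedule is None:
        schedule = default_shift_schedule()
    span = (0.0, days * DAY)
    seeds = child_seeds(seed, n_cd1 + n_lab)
    groups: dict[str, dict] = {}
    for label, profile, count, offs in (
        ("CD1", cd1, n_cd1, 0),
        ("LAB", lab, n_lab, n_cd1),
    ):
        traces = [
            simulate_mouse(profile, schedule, span, seeds[offs + i], f"{label.lower()}_{i + 1}")
            for i in range(count)
        ]
        binned = [acto.bin_activity(tr, bin_width=HOUR, n_days=days) for tr in traces]
        group = acto.group_actogram(binned)
        daily = np.vstack([acto.daily_totals(b) for b in binned])
        windows = {
            name: np.vstack([acto.window_activity(b, win) for b in binned])
            for name, win in (("A", (2, 8)), ("B", (8, 14)), ("C", (14, 20)))
        }
        mod = [acto.modulation(b, schedule) for b in binned]
        pre = np.mean([acto.daily_profile(b, [0, 1]) for b in binned], axis=0)
        post = np.mean([acto.daily_profile(b, [4, 5]) for b in binned], axis=0)
        shift = acto.estimate_phase_shift(pre, post)
        groups[label] = {
            "traces": traces,
            "binned": binned,
            "actogram": group,
            "daily_totals": daily,
            "windows": windows,
            "modulation": mod,
            "phase_shift_h": shift,
        }
    ratio = float(
        np.mean(groups["LAB"]["daily_totals"]) / np.mean(groups["CD1"]["daily_totals"])
    )
    return {
        "schedule": schedule,
        "groups": groups,
        "summary": {
            "cd1_phase_shift_h": groups["CD1"]["phase_shift_h"],
            "lab_phase_shift_h": groups["LAB"]["phase_shift_h"],
            "lab_over_cd1_daily_activity": ratio,
        },
    }


PRESETS = {
    "clock-validation": clock_validation,
    "crosstalk-shielding": crosstalk_shielding,
    "circadian-shift": circadian_shift,
}
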