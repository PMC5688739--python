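"""Synthetic motion-event streams.

Two generators cover the inputs the downstream analyses expect:

* :func:`simulate_mouse` — circadian home-cage activity as an inhomogeneous
  Poisson process.  The animal carries an internal circadian phase (the clock
  hour of its subjective dark onset); the event rate is ``rate_active`` during
  subjective dark and ``rate_rest`` otherwise, both scaled by
  ``activity_scale``.  Photoentrainment is modeled as a discrete, once-per-day
  proportional correction of the phase toward the light schedule's dark onset
  (``entrainment_rate`` is the fraction of the remaining signed error, wrapped
  to (−12, +12] h, removed each day).  This is deliberately the simplest model
  with a single recoverable entrainment parameter; it reproduces day-resolution
  re-entrainment after a schedule shift without an oscillator ODE.

* :func:`simulate_clock` — the analog-clock benchmark: a wall clock with a
  foil flag on the second hand ticks nominally once per second in front of the
  detector.  Ticks may be missed, timestamps carry Gaussian jitter, and the
  tick intervals can carry a sinusoidal modulation (gear slack makes the flag
  vibrate with the hand's rotation period).

All randomness flows through :func:`numpy.random.default_rng` seeded from the
caller's integer seed; a fixed seed yields bit-identical event lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lightcycle import DAY, HOUR, LightSchedule


@dataclass(frozen=True)
class StrainProfile:
    """Rate/entrainment parameters of a simulated mouse line.

    rate_active/rate_rest are events per second during the subjective dark
    (behaviorally active) and rest phases; activity_scale is a dimensionless
    multiplier on both; entrainment_rate in [0, 1] is the per-day fraction of
    the remaining phase error corrected; phase0 is the initial internal dark
    onset in clock hours (None → start aligned with the schedule).
    """

    name: str
    rate_active: float = 0.5
    rate_rest: float = 0.05
    activity_scale: float = 1.0
    entrainment_rate: float = 0.8
    phase0: float | None = None

    def __post_init__(self) -> None:
        if not self.rate_active > self.rate_rest >= 0:
            raise ValueError("require rate_active > rate_rest >= 0")
        if not 0 <= self.entrainment_rate <= 1:
            raise ValueError("entrainment_rate must lie in [0, 1]")
        if self.activity_scale <= 0:
            raise ValueError("activity_scale must be positive")


#: Calibrated strain defaults.  Rates are chosen so a well-entrained animal
#: concentrates >90% of events in the dark phase; the LAB-like line doubles
#: overall activity (hyperactivity) and does not entrain at all within the
#: observation window.
CD1_LIKE = StrainProfile("CD1-like", rate_active=0.5, rate_rest=0.05,
                         activity_scale=1.0, entrainment_rate=0.8)
LAB_LIKE = StrainProfile("LAB-like", rate_active=0.5, rate_rest=0.05,
                         activity_scale=2.0, entrainment_rate=0.0)


@dataclass(frozen=True)
class ClockSimSpec:
    """Parameters of the analog-clock validation stream (seconds throughout)."""

    duration: float = 1800.0
    tick_interval: float = 1.0
    timestamp_jitter_sd: float = 0.0
    miss_probability: float = 0.0
    modulation_period: float = 0.0
    modulation_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.tick_interval <= 0:
            raise ValueError("duration and tick_interval must be positive")
        if not 0 <= self.miss_probability < 1:
            raise ValueError("miss_probability must lie in [0, 1)")
        if self.timestamp_jitter_sd < 0 or self.modulation_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.modulation_amplitude > 0 and self.modulation_period <= 0:
            raise ValueError("modulation_amplitude > 0 requires a positive period")


@dataclass(frozen=True)
class ActivityTrace:
    """Simulated ground-truth event stream for one animal (or the clock)."""

    animal_id: str
    event_times: np.ndarray  # strictly increasing, seconds
    schedule: LightSchedule | None
    seed: int
    phase_by_day: np.ndarray | None = None  # internal dark onset, clock hours

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("event_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.event_times.size)


def wrap_phase_error(delta_hours: float) -> float:
    """Wrap a signed phase difference to (−12, +12] h."""
    w = (delta_hours + 12.0) % 24.0 - 12.0
    return 12.0 if w == -12.0 else w


def entrainment_phases(
    profile: StrainProfile, schedule: LightSchedule, n_days: int
) -> np.ndarray:
    """Internal dark-onset phase (clock hours) for days 0..n_days-1.

    The phase is updated at each midnight toward that day's schedule dark
    onset; days whose dark onset was displaced off the calendar day by a shift
    reuse the most recent known onset.
    """
    phases = np.empty(n_days)
    target = schedule.dark_onset_hour(0)
    if target is None:
        target = schedule.light_off_at
    phases[0] = profile.phase0 if profile.phase0 is not None else target
    for d in range(1, n_days):
        onset = schedule.dark_onset_hour(d)
        if onset is not None:
            target = onset
        err = wrap_phase_error(target - phases[d - 1])
        phases[d] = (phases[d - 1] + profile.entrainment_rate * err) % 24.0
    return phases


def simulate_mouse(
    profile: StrainProfile,
    schedule: LightSchedule,
    span: tuple[float, float],
    seed: int,
    animal_id: str | None = None,
) -> ActivityTrace:
    """Draw one animal's event stream over ``span`` (seconds).

    Inhomogeneous Poisson process via thinning: candidates are drawn at the
    maximal rate and accepted with probability rate(t)/rate_max, where rate(t)
    depends on whether the clock hour of t falls in the animal's subjective
    dark window [phase, phase + dark_duration) for that day.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must be non-empty")
    rng = np.random.default_rng(seed)
    n_days = int(np.ceil(t1 / DAY))
    phases = entrainment_phases(profile, schedule, max(n_days, 1))
    dark_len = schedule.dark_duration_hours

    rate_hi = profile.activity_scale * profile.rate_active
    rate_lo = profile.activity_scale * profile.rate_rest
    n_cand = rng.poisson(rate_hi * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))

    day_idx = np.minimum((cand // DAY).astype(int), len(phases) - 1)
    clock_h = (cand % DAY) / HOUR
    in_dark = (clock_h - phases[day_idx]) % 24.0 < dark_len
    rates = np.where(in_dark, rate_hi, rate_lo)
    keep = rng.uniform(0.0, rate_hi, n_cand) < rates
    times = np.unique(cand[keep])
    return ActivityTrace(
        animal_id=animal_id or profile.name,
        event_times=times,
        schedule=schedule,
        seed=seed,
        phase_by_day=phases,
    )


def simulate_homogeneous(
    rate: float, span: tuple[float, float], seed: int, animal_id: str = "homogeneous"
) -> ActivityTrace:
    """Constant-rate Poisson event stream (crosstalk/bench experiments)."""
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must be non-empty")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * (t1 - t0))
    times = np.unique(np.sort(rng.uniform(t0, t1, n)))
    return ActivityTrace(animal_id, times, None, seed)


def simulate_clock(spec: ClockSimSpec, seed: int) -> ActivityTrace:
    """Simulate the clock-hand benchmark recording.

    Nominal tick k sits at k·tick_interval; the k-th interval is lengthened by
    ``modulation_amplitude * sin(2π · k · tick_interval / modulation_period)``
    (a peak interval deviation, emulating flag vibration at the hand's
    rotation period); each surviving tick's timestamp then receives Gaussian
    jitter.  With all noise at zero the output is exactly the tick grid.
    """
    n = int(round(spec.duration / spec.tick_interval))
    rng = np.random.default_rng(seed)
    intervals = np.full(n, spec.tick_interval)
    if spec.modulation_amplitude > 0:
        k = np.arange(n)
        intervals = intervals + spec.modulation_amplitude * np.sin(
            2 * np.pi * k * spec.tick_interval / spec.modulation_period
        )
    times = np.cumsum(intervals)
    if spec.timestamp_jitter_sd > 0:
        times = times + rng.normal(0.0, spec.timestamp_jitter_sd, n)
    if spec.miss_probability > 0:
        times = times[rng.random(n) >= spec.miss_probability]
    times = np.unique(times)
    return ActivityTrace("clock", times, None, seed)
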