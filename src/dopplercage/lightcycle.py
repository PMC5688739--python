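"""Light/dark schedules with phase shifts.

A :class:`LightSchedule` describes the housing-room lighting as a binary
state (LIGHT/DARK) over experiment time.  Time is measured in seconds from
midnight of the first experimental day (t = 0).  Clock times of the light-on
and light-off transitions are given in hours; the default schedule is the
inverted 12 h/12 h cycle used for the circadian experiments (lights ON at
8 PM, OFF at 8 AM, so the animals' dark phase falls in the working day).

Schedule shifts (e.g. a −6 h phase advance) are expressed as
``(effective_time_s, offset_hours)`` pairs: every nominal transition lying
strictly after the effective time is moved by the offset.  With the
effective time placed at a dark onset, a negative offset shortens that dark
phase — the light phase returns early — which is how an advance is applied
to a running animal experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

HOUR = 3600.0
DAY = 86400.0


class LightState(Enum):
    LIGHT = "LIGHT"
    DARK = "DARK"


@dataclass(frozen=True)
class Transition:
    time: float
    new_state: LightState

    @property
    def direction(self) -> str:
        return "DARK->LIGHT" if self.new_state is LightState.LIGHT else "LIGHT->DARK"


@dataclass(frozen=True)
class LightSchedule:
    """Binary light schedule with optional phase shifts.

    Parameters
    ----------
    light_on_at, light_off_at : float
        Clock hours of the transitions, in [0, cycle_length).  Defaults give
        the inverted cycle: ON 20:00, OFF 08:00.
    cycle_length : float
        Period of the schedule in hours (24 for all supported protocols).
    shifts : tuple of (float, float)
        ``(effective_time_s, offset_hours)``; transitions strictly after the
        effective time move by the offset.  Strictly increasing effective
        times.
    start : float
        Start of the defined span, seconds (default 0 = midnight of day 1).
        Queries before ``start`` raise.
    """

    light_on_at: float = 20.0
    light_off_at: float = 8.0
    cycle_length: float = 24.0
    shifts: tuple[tuple[float, float], ...] = ()
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        for name in ("light_on_at", "light_off_at"):
            v = getattr(self, name)
            if not 0 <= v < self.cycle_length:
                raise ValueError(f"{name}={v} outside [0, {self.cycle_length})")
        if self.light_on_at == self.light_off_at:
            raise ValueError("light_on_at and light_off_at must differ")
        times = [t for t, _ in self.shifts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("shift effective times must be strictly increasing")
        if any(t <= self.start for t in times):
            raise ValueError("shift effective times must lie after schedule start")

    # -- construction helpers -------------------------------------------------

    def shifted_on_day(self, day: int, offset_hours: float) -> "LightSchedule":
        """Return a copy with an additional shift applied on 1-based ``day``.

        The shift becomes effective at that day's nominal dark onset
        (``light_off_at``), so an advance shortens that day's dark phase.
        """
        eff = (day - 1) * DAY + self.light_off_at * HOUR
        return LightSchedule(
            self.light_on_at,
            self.light_off_at,
            self.cycle_length,
            self.shifts + ((eff, offset_hours),),
            self.start,
        )

    # -- internals ------------------------------------------------------------

    def _offset_at(self, nominal_time: float) -> float:
        """Cumulative shift offset (s) for a transition at a nominal time."""
        return sum(off * HOUR for eff, off in self.shifts if nominal_time > eff)

    def _nominal_state(self, t: float) -> LightState:
        h = (t / HOUR) % self.cycle_length
        on, off = self.light_on_at, self.light_off_at
        if on < off:
            light = on <= h < off
        else:
            light = h >= on or h < off
        return LightState.LIGHT if light else LightState.DARK

    def _all_transitions_until(self, t_end: float) -> list[Transition]:
        cyc = self.cycle_length * HOUR
        # generous margin so shifted transitions near t_end are not missed
        margin = cyc + sum(abs(off) * HOUR for _, off in self.shifts)
        n_cycles = max(0, math.ceil((t_end + margin - self.start) / cyc)) + 1
        k0 = math.floor(self.start / cyc) - 1
        out: list[Transition] = []
        for k in range(k0, k0 + n_cycles + 2):
            for clock_h, state in (
                (self.light_on_at, LightState.LIGHT),
                (self.light_off_at, LightState.DARK),
            ):
                nominal = k * cyc + clock_h * HOUR
                actual = nominal + self._offset_at(nominal)
                if self.start <= actual <= t_end:
                    out.append(Transition(actual, state))
        out.sort(key=lambda tr: tr.time)
        for a, b in zip(out, out[1:]):
            if b.time <= a.time:
                raise ValueError(
                    "shift offsets reorder transitions; offset exceeds phase length"
                )
        return out

    # -- queries --------------------------------------------------------------

    def light_state(self, t: float) -> LightState:
        """State at absolute time ``t`` (s).  Transition instants belong to
        the new state (half-open [on, off) convention)."""
        if t < self.start:
            raise ValueError(f"t={t} precedes schedule start {self.start}")
        trs = self._all_transitions_until(t)
        if trs:
            return trs[-1].new_state
        return self._nominal_state(self.start)

    def transitions(self, span: tuple[float, float]) -> list[Transition]:
        """Transitions with time in half-open ``[span[0], span[1])``."""
        a, b = span
        if b <= a:
            return []
        return [tr for tr in self._all_transitions_until(b) if a <= tr.time < b]

    def state_at_times(self, times) -> "np.ndarray":
        """Vectorized :meth:`light_state`: boolean array, True where LIGHT."""
        import numpy as np

        t = np.asarray(times, dtype=float)
        if t.size == 0:
            return np.zeros(0, dtype=bool)
        if t.min() < self.start:
            raise ValueError("times precede schedule start")
        trs = self._all_transitions_until(float(t.max()))
        tr_times = np.array([tr.time for tr in trs])
        tr_light = np.array([tr.new_state is LightState.LIGHT for tr in trs])
        init = self._nominal_state(self.start) is LightState.LIGHT
        idx = np.searchsorted(tr_times, t, side="right")
        states = np.concatenate(([init], tr_light))
        return states[idx]

    def dark_onset_hour(self, day: int) -> float | None:
        """Clock hour of the LIGHT→DARK transition on 0-based ``day``.

        None when a shift removed the dark onset from that calendar day.
        """
        span = (max(self.start, day * DAY), (day + 1) * DAY)
        for tr in self.transitions(span):
            if tr.new_state is LightState.DARK:
                return (tr.time % DAY) / HOUR
        return None

    @property
    def dark_duration_hours(self) -> float:
        """Nominal (unshifted) dark-phase length per cycle, hours."""
        return (self.light_on_at - self.light_off_at) % self.cycle_length


def light_state(schedule: LightSchedule, t: float) -> LightState:
    return schedule.light_state(t)


def transitions(schedule: LightSchedule, span: tuple[float, float]) -> list[Transition]:
    return schedule.transitions(span)
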