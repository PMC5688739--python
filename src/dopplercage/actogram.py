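"""Actograms and circadian photoentrainment statistics.

Activity is binned on a regular grid anchored at midnight of the first
experimental day (1 h bins by default, so each day folds into one actogram
row of 24 bins).  On top of the binned counts the module computes group
mean ± SEM actograms, daily totals, clock-window totals (the A/B/C 6-h
windows of the shift experiment), the light-transition modulation statistic
(activity in the 3 h after a transition as a percentage of the 3 h before),
and a circular cross-correlation estimator of the schedule phase shift
expressed by the activity profile.  Sign convention: negative = phase
advance (activity onset moves to an earlier clock time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import EventLog
from .lightcycle import DAY, HOUR, LightSchedule, LightState
from .synthetic import ActivityTrace


@dataclass(frozen=True)
class BinnedActivity:
    """Per-animal event counts on a regular grid starting at t = 0 (midnight
    of day 1); ``bin_width`` in seconds must divide the day evenly."""

    animal_id: str
    bin_width: float
    counts: np.ndarray
    schedule: LightSchedule | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if round(DAY / self.bin_width, 9) % 1 != 0:
            raise ValueError("bin_width must divide 24 h evenly")
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def bins_per_day(self) -> int:
        return int(round(DAY / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.counts.size + 1) * self.bin_width

    @property
    def n_full_days(self) -> int:
        return self.counts.size // self.bins_per_day


@dataclass(frozen=True)
class GroupActogram:
    """Group mean and SEM actogram, day rows × within-day bins."""

    mean: np.ndarray
    sem: np.ndarray
    n_animals: int
    bin_width: float


def _event_times(source: EventLog | ActivityTrace, channel) -> np.ndarray:
    if isinstance(source, ActivityTrace):
        return source.event_times
    if channel is None:
        raise ValueError("channel required for EventLog input")
    return source.times(channel)


def bin_activity(
    source: EventLog | ActivityTrace,
    channel: int | str | None = None,
    bin_width: float = HOUR,
    n_days: int | None = None,
    animal_id: str | None = None,
) -> BinnedActivity:
    """Bin one channel's events onto the midnight-anchored grid.

    Half-open bins; the grid covers ``n_days`` whole days (default: the
    smallest whole number of days containing the last event).  Counts are
    conserved: their sum equals the number of events inside the grid.
    """
    times = _event_times(source, channel)
    if n_days is None:
        n_days = max(1, int(np.ceil((times.max() + 1e-9) / DAY))) if times.size else 1
    edges = np.arange(int(round(n_days * DAY / bin_width)) + 1) * bin_width
    idx = np.floor(times / bin_width).astype(np.int64)
    keep = (idx >= 0) & (idx < len(edges) - 1)
    counts = np.bincount(idx[keep], minlength=len(edges) - 1)
    if animal_id is None:
        animal_id = (
            source.animal_id if isinstance(source, ActivityTrace) else str(channel)
        )
    schedule = source.schedule if isinstance(source, ActivityTrace) else None
    return BinnedActivity(animal_id, bin_width, counts, schedule)


def group_actogram(members: list[BinnedActivity]) -> GroupActogram:
    """Elementwise mean and SEM (sample sd / sqrt(n), across animals per
    bin) folded into day rows.  n = 1 reports SEM 0 with a warning."""
    if not members:
        raise ValueError("no animals")
    shapes = {(m.counts.size, m.bin_width) for m in members}
    if len(shapes) != 1:
        raise ValueError("members must share an identical bin grid")
    stack = np.vstack([m.counts for m in members]).astype(float)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n == 1:
        warnings.warn("single animal: SEM undefined, reporting 0")
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    bpd = members[0].bins_per_day
    days = mean.size // bpd
    shape = (days, bpd)
    return GroupActogram(
        mean[: days * bpd].reshape(shape),
        sem[: days * bpd].reshape(shape),
        n,
        members[0].bin_width,
    )


def daily_totals(binned: BinnedActivity) -> np.ndarray:
    """Total counts per whole day; a partial trailing day is excluded (with a
    warning naming how many bins were dropped)."""
    bpd = binned.bins_per_day
    days = binned.counts.size // bpd
    extra = binned.counts.size - days * bpd
    if extra:
        warnings.warn(f"excluding partial trailing day ({extra} bins)")
    return binned.counts[: days * bpd].reshape(days, bpd).sum(axis=1)


def window_activity(
    binned: BinnedActivity, window: tuple[float, float]
) -> np.ndarray:
    """Per-day counts inside a daily clock window (hours, e.g. (14, 20)).

    The window must align with bin edges and lie within the day.
    """
    lo_h, hi_h = window
    if not 0 <= lo_h < hi_h <= 24:
        raise ValueError("window must lie within the day, lo < hi")
    w_h = binned.bin_width / HOUR
    lo, hi = lo_h / w_h, hi_h / w_h
    if round(lo, 9) % 1 != 0 or round(hi, 9) % 1 != 0:
        raise ValueError("window must align with bin edges")
    lo, hi = int(round(lo)), int(round(hi))
    bpd = binned.bins_per_day
    days = binned.counts.size // bpd
    folded = binned.counts[: days * bpd].reshape(days, bpd)
    return folded[:, lo:hi].sum(axis=1)


def modulation(
    source: EventLog | ActivityTrace | BinnedActivity,
    schedule: LightSchedule,
    window: float = 3 * HOUR,
    channel: int | str | None = None,
    span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Light-transition modulation: activity in the ``window`` after each
    light transition as a percentage of the ``window`` before.

    Returns a DataFrame with columns ``time`` (s), ``direction``, ``pre``,
    ``post`` and ``modulation_pct`` (NaN where the pre-window is empty —
    no division by zero).  Only transitions with a full window of data on
    both sides are evaluated.
    """
    if isinstance(source, BinnedActivity):
        if round(window / source.bin_width, 9) % 1 != 0:
            raise ValueError("window must be a whole number of bins")
        counts = source.counts
        w_bins = int(round(window / source.bin_width))

        def _count(a: float, b: float) -> float:
            i, j = a / source.bin_width, b / source.bin_width
            if round(i, 9) % 1 != 0 or round(j, 9) % 1 != 0:
                raise ValueError("transition not aligned with bin edges")
            return float(counts[int(round(i)) : int(round(j))].sum())

        total_span = (0.0, counts.size * source.bin_width)
    else:
        times = _event_times(source, channel)

        def _count(a: float, b: float) -> float:
            return float(np.searchsorted(times, b) - np.searchsorted(times, a))

        total_span = (0.0, float(times.max()) if times.size else 0.0)
    if span is None:
        span = total_span
    rows = []
    for tr in schedule.transitions((span[0] + window, span[1] - window + 1e-9)):
        pre = _count(tr.time - window, tr.time)
        post = _count(tr.time, tr.time + window)
        pct = 100.0 * post / pre if pre > 0 else np.nan
        rows.append(
            {"time": tr.time, "direction": tr.direction, "pre": pre,
             "post": post, "modulation_pct": pct}
        )
    return pd.DataFrame(rows, columns=["time", "direction", "pre", "post", "modulation_pct"])


def daily_profile(binned: BinnedActivity, days: list[int]) -> np.ndarray:
    """Mean within-day profile over the given 0-based days (length = bins/day)."""
    bpd = binned.bins_per_day
    folded = binned.counts[: binned.n_full_days * bpd].reshape(-1, bpd)
    bad = [d for d in days if not 0 <= d < folded.shape[0]]
    if bad:
        raise ValueError(f"days {bad} outside the recorded span")
    return folded[days].mean(axis=0)


def estimate_phase_shift(
    profile_pre: np.ndarray, profile_post: np.ndarray, bin_width: float = HOUR
) -> float:
    """Schedule shift (signed hours) expressed by the post profile relative
    to the pre profile, by circular cross-correlation over all rotations.

    The returned shift s satisfies post(h) ≈ pre(h − s); activity moving to
    an earlier clock time (an advance) therefore yields a negative s.  The
    result lies in (−12, +12] h; ties are broken toward the smallest |s|
    (an advance wins over the equal-magnitude delay).
    """
    pre = np.asarray(profile_pre, dtype=float)
    post = np.asarray(profile_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("profiles must be 1-D and share a grid")
    if np.std(pre) == 0 or np.std(post) == 0:
        raise ValueError("flat profile: phase shift undefined")
    n = pre.size
    corr = np.empty(n)
    zp = (post - post.mean()) / post.std()
    for s in range(n):
        rolled = np.roll(pre, s)
        corr[s] = np.mean(zp * (rolled - rolled.mean()) / rolled.std())
    best = np.max(corr)
    hours_per_bin = bin_width / HOUR
    cands = []
    for s in np.flatnonzero(np.isclose(corr, best, atol=1e-12)):
        h = s * hours_per_bin
        half = n * hours_per_bin / 2
        if h > half:
            h -= n * hours_per_bin
        cands.append(h)
    cands.sort(key=lambda h: (abs(h), h))
    return float(cands[0])
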