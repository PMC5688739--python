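"""Motion Detector Shield emulation and the CSV log format.

The physical chain being modeled: each cage's X-band Doppler module emits
microsecond pulses on movement; a retriggerable monostable multivibrator
stretches them to >= 1 s pulses; any pulse edge raises an interrupt, the
firmware polls all six channel lines, writes one CSV row (RTC timestamp at
1 s resolution, six 0/1 channel flags, 10-bit ambient-light reading) and
resets the multivibrators.  Neighboring cages can pick up each other's motion
(crosstalk) unless a grounded-free aluminum-foil shield sits between them,
which eliminates pickup completely.

:func:`extend_pulses` is the multivibrator (interval-union) model,
:func:`log_events` the interrupt/log/reset cycle over a cage array, and
:func:`write_csv`/:func:`read_csv` the on-disk format
(``datetime,ch1..ch6,light``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lightcycle import LightSchedule, LightState
from .synthetic import ActivityTrace

N_CHANNELS = 6
CHANNEL_COLUMNS = [f"ch{i}" for i in range(1, N_CHANNELS + 1)]
CSV_COLUMNS = ["datetime", *CHANNEL_COLUMNS, "light"]
DATETIME_FORMAT = "%Y-%m-%d %H:%M:%S"

#: 10-bit light-sensor readings emitted for the two schedule states.
LIGHT_RAW_LIGHT = 920
LIGHT_RAW_DARK = 8


class CsvFormatError(ValueError):
    """Malformed log file; message names the offending line."""


@dataclass
class EventLog:
    """Time-ordered detector records.

    ``frame`` columns: ``datetime`` (second resolution), ``ch1``..``ch6``
    (0/1), ``light`` (0..1023).  Every record flags at least one channel —
    rows are only written after an interrupt.
    """

    frame: pd.DataFrame
    channel_labels: tuple[str, ...] = tuple(CHANNEL_COLUMNS)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"EventLog frame missing columns {missing}")
        f = self.frame
        if len(f):
            flags = f[list(CHANNEL_COLUMNS)].to_numpy()
            if not np.isin(flags, (0, 1)).all():
                raise ValueError("channel flags must be 0/1")
            bad = np.flatnonzero(flags.sum(axis=1) == 0)
            if bad.size:
                raise ValueError(
                    f"record {bad[0]} flags no channel; records are only "
                    "written after an interrupt"
                )
            light = f["light"].to_numpy()
            if light.min() < 0 or light.max() > 1023:
                raise ValueError("light readings must lie in the 10-bit range 0..1023")
            ts = f["datetime"].to_numpy()
            if not (ts[:-1] <= ts[1:]).all():
                raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def origin(self) -> pd.Timestamp:
        """Midnight of the first record's calendar day."""
        if not len(self.frame):
            raise ValueError("empty log has no origin")
        return self.frame["datetime"].iloc[0].normalize()

    def times(self, channel: int | str, origin: pd.Timestamp | None = None) -> np.ndarray:
        """Event times (s) of records flagging ``channel``, relative to
        ``origin`` (default: midnight of the first record's day)."""
        col = _channel_column(channel)
        if origin is None:
            origin = self.origin
        sel = self.frame.loc[self.frame[col] == 1, "datetime"]
        return (sel - origin).dt.total_seconds().to_numpy()

    def flag_count(self, channel: int | str) -> int:
        return int(self.frame[_channel_column(channel)].sum())


def _channel_column(channel: int | str) -> str:
    if isinstance(channel, (int, np.integer)):
        col = f"ch{int(channel)}"
    else:
        col = str(channel)
    if col not in CHANNEL_COLUMNS:
        raise ValueError(f"unknown channel {channel!r}; expected 1..6 or ch1..ch6")
    return col


@dataclass
class CageArray:
    """Occupancy and coupling of up to six simultaneously logged cages.

    ``crosstalk[i, j]`` is the probability that the channel-(i+1) detector
    registers a physical event occurring in cage j+1 (diagonal = 1: a
    detector always sees its own cage).  ``shields`` is a set of unordered
    cage pairs separated by foil; their effective pickup is forced to 0.
    """

    occupancy: dict[int, ActivityTrace] = field(default_factory=dict)
    crosstalk: np.ndarray = field(default_factory=lambda: np.eye(N_CHANNELS))
    shields: frozenset[frozenset[int]] = frozenset()

    def __post_init__(self) -> None:
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if self.crosstalk.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("crosstalk must be a 6x6 matrix")
        if not np.allclose(np.diag(self.crosstalk), 1.0):
            raise ValueError("crosstalk diagonal must be 1")
        if self.crosstalk.min() < 0 or self.crosstalk.max() > 1:
            raise ValueError("crosstalk entries must lie in [0, 1]")
        for ch in self.occupancy:
            if not 1 <= ch <= N_CHANNELS:
                raise ValueError(f"occupied channel {ch} outside 1..6")
        self.shields = frozenset(frozenset(p) for p in self.shields)

    def pickup(self, listener: int, source: int) -> float:
        if frozenset((listener, source)) in self.shields and listener != source:
            return 0.0
        return float(self.crosstalk[listener - 1, source - 1])


def extend_pulses(
    event_times, hold: float = 1.0
) -> list[tuple[float, float]]:
    """Retriggerable-monostable pulse extension.

    Returns the disjoint sorted union of [t, t + hold) over the events: each
    event restarts the hold, so bursts merge into one long pulse.
    """
    t = np.asarray(event_times, dtype=float)
    if hold <= 0:
        raise ValueError("hold must be positive")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("event_times must be sorted ascending")
    out: list[tuple[float, float]] = []
    for ti in t:
        if out and ti < out[-1][1]:
            out[-1] = (out[-1][0], ti + hold)
        else:
            out.append((ti, ti + hold))
    return out


def log_events(
    cages: CageArray,
    seed: int,
    dead_time: float = 0.1,
    hold: float = 1.0,
    start: str | pd.Timestamp = "2024-01-01 00:00:00",
    schedule: LightSchedule | None = None,
) -> EventLog:
    """Run the interrupt/log/reset cycle over the cage array's event streams.

    Each physical event is copied onto every other channel independently with
    that channel's pickup probability (0 across a shield).  The merged stream
    is swept in time order: an event arriving at least ``dead_time`` after the
    previously written record triggers a new record whose flags are all
    channels with a pulse still high at the poll — an event inside
    ``(max(t − hold, t_previous_record), t]``; the lower cut at the previous
    record models the multivibrator reset after each SD write.  Simultaneous
    events (e.g. crosstalk copies) are flagged in the same record.  Events
    landing inside the dead time trigger no record of their own (the firmware
    is busy writing) but remain visible to the next poll.  Timestamps are
    floored to whole seconds, mimicking the RTC.  ``schedule``, when given,
    drives the ambient-light column; otherwise light reads 0.
    """
    if not any(len(tr) for tr in cages.occupancy.values()):
        raise ValueError("all cages empty; nothing to log")
    if dead_time <= 0:
        raise ValueError("dead_time must be positive")
    rng = np.random.default_rng(seed)

    times_parts: list[np.ndarray] = []
    chan_parts: list[np.ndarray] = []
    for source in sorted(cages.occupancy):
        tr = cages.occupancy[source]
        t = tr.event_times
        if not t.size:
            continue
        times_parts.append(t)
        chan_parts.append(np.full(t.size, source, dtype=np.int64))
        for listener in range(1, N_CHANNELS + 1):
            if listener == source:
                continue
            p = cages.pickup(listener, source)
            if p <= 0:
                continue
            picked = t[rng.random(t.size) < p]
            if picked.size:
                times_parts.append(picked)
                chan_parts.append(np.full(picked.size, listener, dtype=np.int64))

    times = np.concatenate(times_parts)
    chans = np.concatenate(chan_parts)
    order = np.argsort(times, kind="stable")
    times, chans = times[order], chans[order]

    start = pd.Timestamp(start)
    rows_t: list[float] = []
    rows_flags: list[np.ndarray] = []
    last_trigger = -np.inf
    for i in range(times.size):
        t = times[i]
        if t - last_trigger < dead_time:
            continue
        lo = np.searchsorted(times, max(t - hold, last_trigger), side="right")
        hi = np.searchsorted(times, t, side="right")
        flags = np.zeros(N_CHANNELS, dtype=np.int64)
        flags[chans[lo:hi] - 1] = 1
        rows_t.append(t)
        rows_flags.append(flags)
        last_trigger = t

    dt = start + pd.to_timedelta(np.floor(rows_t).astype(np.int64), unit="s")
    flags_arr = np.vstack(rows_flags)
    if schedule is not None:
        lit = schedule.state_at_times(np.asarray(rows_t))
        light = np.where(lit, LIGHT_RAW_LIGHT, LIGHT_RAW_DARK)
    else:
        light = np.zeros(len(rows_t), dtype=np.int64)
    frame = pd.DataFrame({"datetime": dt})
    for j, col in enumerate(CHANNEL_COLUMNS):
        frame[col] = flags_arr[:, j]
    frame["light"] = light
    return EventLog(frame)


def activity_per_minute(
    log: EventLog,
    channel: int | str,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> pd.Series:
    """Detector activations per wall-clock minute for one channel.

    The conventional "activity per minute" readout: the count of
    records flagging the channel in each minute bin; minutes without records
    are zero.  ``span`` (start, end) widens/narrows the minute grid; by
    default it covers first to last record.
    """
    col = _channel_column(channel)
    ts = pd.to_datetime(log.frame.loc[log.frame[col] == 1, "datetime"])
    if span is None:
        if not len(log.frame):
            return pd.Series(dtype=np.int64)
        lo = log.frame["datetime"].iloc[0].floor("min")
        hi = log.frame["datetime"].iloc[-1].floor("min")
        index = pd.date_range(lo, hi, freq="min")
    else:
        lo = pd.Timestamp(span[0]).floor("min")
        end = pd.Timestamp(span[1])
        index = pd.date_range(lo, end, freq="min", inclusive="left")
    counts = ts.dt.floor("min").value_counts()
    return counts.reindex(index, fill_value=0).astype(np.int64)


def write_csv(log: EventLog, path) -> None:
    """Write the log in the fixed on-disk schema (lossless round trip)."""
    out = log.frame.copy()
    if len(out):
        out["datetime"] = out["datetime"].dt.strftime(DATETIME_FORMAT)
    out.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_csv(path) -> EventLog:
    """Read a detector log; malformed rows raise :class:`CsvFormatError`
    naming the line, non-monotone timestamps warn and are stably re-sorted."""
    try:
        frame = pd.read_csv(path, dtype={c: "Int64" for c in CHANNEL_COLUMNS + ["light"]})
    except pd.errors.ParserError as exc:
        raise CsvFormatError(f"unparseable CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CsvFormatError(f"missing columns {missing}")
    frame = frame[CSV_COLUMNS]
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        vals = row[1:]
        if any(pd.isna(v) for v in vals):
            raise CsvFormatError(f"line {lineno}: missing value")
        if any(v not in (0, 1) for v in vals[:-1]):
            raise CsvFormatError(f"line {lineno}: channel flags must be 0/1")
        if sum(vals[:-1]) == 0:
            raise CsvFormatError(f"line {lineno}: record flags no channel")
        if not 0 <= vals[-1] <= 1023:
            raise CsvFormatError(f"line {lineno}: light outside 0..1023")
    try:
        frame["datetime"] = pd.to_datetime(frame["datetime"], format=DATETIME_FORMAT)
    except (ValueError, TypeError) as exc:
        raise CsvFormatError(f"bad timestamp: {exc}") from exc
    for c in CHANNEL_COLUMNS + ["light"]:
        frame[c] = frame[c].astype(np.int64)
    ts = frame["datetime"].to_numpy()
    if len(ts) > 1 and not (ts[:-1] <= ts[1:]).all():
        warnings.warn("non-monotone timestamps; re-sorting records stably")
        frame = frame.sort_values("datetime", kind="stable", ignore_index=True)
    return EventLog(frame.reset_index(drop=True))
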