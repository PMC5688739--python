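"""Inter-event interval statistics for detector validation.

The bench validation of the detector records a ticking analog clock and asks:
are events spaced 1 s apart, how tight is that spacing (summary statistics,
histogram, fraction within 950–1050 ms), and is there a slower rhythm hiding
in the interval sequence (autocorrelation; the clock's gear slack shows up at
the 1-min rotation period of the second hand)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .device import EventLog
from .synthetic import ActivityTrace


@dataclass(frozen=True)
class IntervalSeries:
    """Ordered inter-event intervals (s) from one channel.

    Intervals are non-negative; zeros can occur when the source is an
    EventLog, whose RTC timestamps are quantized to 1 s and may tie.
    """

    intervals: np.ndarray
    source_channel: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.size and iv.min() < 0:
            raise ValueError("intervals must be non-negative")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class IntervalSummary:
    n_events: int
    mean: float
    median: float
    percentiles: dict[float, float]


def intervals(source: EventLog | ActivityTrace, channel: int | str | None = None) -> IntervalSeries:
    """Successive differences of event times.

    For an :class:`EventLog` the 1 s RTC timestamps of the given channel are
    used; an :class:`ActivityTrace` supplies its high-resolution times
    directly.
    """
    if isinstance(source, ActivityTrace):
        times = source.event_times
        label = source.animal_id
    else:
        if channel is None:
            raise ValueError("channel required for EventLog input")
        times = source.times(channel)
        label = f"ch{channel}" if isinstance(channel, int) else str(channel)
    if times.size < 2:
        raise ValueError("need at least 2 events to form intervals")
    return IntervalSeries(np.diff(times), label)


def summarize(
    series: IntervalSeries, percentiles: tuple[float, ...] = (5, 25, 75, 95)
) -> IntervalSummary:
    """Mean/median plus requested percentiles (linear interpolation between
    order statistics, the spreadsheet-default convention)."""
    iv = series.intervals
    if not iv.size:
        raise ValueError("empty interval series")
    pcts = {float(p): float(np.percentile(iv, p)) for p in percentiles}
    return IntervalSummary(
        n_events=len(series) + 1,
        mean=float(np.mean(iv)),
        median=float(np.median(iv)),
        percentiles=pcts,
    )


def interval_histogram(
    series: IntervalSeries, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Counts on half-open bins [k·w, (k+1)·w); returns (edges, counts).

    Bin membership is computed by integer division so boundary intervals land
    deterministically in the right-hand bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    iv = series.intervals
    if not iv.size:
        raise ValueError("empty interval series")
    idx = np.floor(iv / bin_width).astype(np.int64)
    k0, k1 = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - k0, minlength=k1 - k0 + 1)
    edges = (np.arange(k0, k1 + 2)) * bin_width
    return edges, counts


def fraction_in_range(series: IntervalSeries, lo: float, hi: float) -> float:
    """Fraction of intervals in half-open [lo, hi)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    iv = series.intervals
    if not iv.size:
        raise ValueError("empty interval series")
    return float(np.mean((iv >= lo) & (iv < hi)))


def interval_autocorrelation(series: IntervalSeries, max_lag: int) -> np.ndarray:
    """Autocorrelation of the interval sequence for lags 0..max_lag.

    Each lag uses the plain Pearson correlation of the overlapping pairs
    (x_t, x_{t+k}) — not the FFT-based biased estimator — so small-n values
    stay bounded and comparable across lags.  Lag 0 is 1 by definition.
    """
    x = series.intervals
    n = x.size
    if n <= max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    if np.var(x) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        a, b = x[:-k], x[k:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            acf[k] = np.nan
            continue
        acf[k] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return acf


def dominant_period(
    series: IntervalSeries,
    min_lag: int = 10,
    max_lag: int | None = None,
) -> float | None:
    """Period (s) of the strongest rhythm in the interval sequence, or None.

    Peak-picking on the lag-domain autocorrelation: the global maximum over
    lags in (min_lag, max_lag] must clear a white-noise detection threshold
    (the 1/sqrt(n) null scale with a Bonferroni correction for the number of
    lags examined, overall two-sided level 1%), otherwise the result is
    "no rhythm" (None).  Because a periodic modulation puts equally high
    peaks at every multiple of its period, the reported lag is the argmax
    among the *earliest* cluster of lags whose correlation comes within one
    3/sqrt(n) band of the global maximum (all such lags up to 1.5x the first
    one) — i.e. the fundamental, not a harmonic.  The lag is converted to
    time via the mean interval.
    """
    from scipy import stats

    x = series.intervals
    n = x.size
    if max_lag is None:
        max_lag = min(n - 3, max(min_lag + 1, n // 4))
    if max_lag <= min_lag:
        raise ValueError("max_lag must exceed min_lag")
    acf = interval_autocorrelation(series, max_lag)
    lags = np.arange(min_lag + 1, max_lag + 1)
    vals = acf[min_lag + 1 :]
    peak = np.nanmax(vals)
    threshold = stats.norm.ppf(1.0 - 0.005 / lags.size) / np.sqrt(n)
    if not peak > threshold:
        return None
    band = 3.0 / np.sqrt(n)
    cand = lags[vals >= peak - band]
    cluster = cand[cand <= 1.5 * cand[0]]
    in_cluster = np.isin(lags, cluster)
    best = lags[in_cluster][int(np.nanargmax(vals[in_cluster]))]
    return float(best * np.mean(x))
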