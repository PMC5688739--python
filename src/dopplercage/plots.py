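"""Figure-style outputs: raster actograms and group overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .actogram import GroupActogram
from .lightcycle import DAY, HOUR, LightSchedule, LightState


def actogram_figure(
    group: GroupActogram,
    schedule: LightSchedule | None = None,
    double_plot: bool = False,
):
    """Raster actogram: one row per day, bars for mean counts; the light
    phase is shaded white, the dark phase gray, when a schedule is given.
    ``double_plot`` appends the following day to each row (48 h rows)."""
    mean = group.mean
    days, bpd = mean.shape
    if double_plot:
        nxt = np.vstack([mean[1:], np.zeros((1, bpd))])
        mean = np.hstack([mean, nxt])
        bpd *= 2
    fig, axes = plt.subplots(days, 1, sharex=True, figsize=(8, 1.0 * days))
    axes = np.atleast_1d(axes)
    hours = np.arange(bpd) * (group.bin_width / HOUR)
    top = mean.max() or 1.0
    for d, ax in enumerate(axes):
        if schedule is not None:
            for b in range(bpd):
                t = d * DAY + b * group.bin_width
                if schedule.light_state(t) is LightState.DARK:
                    ax.axvspan(hours[b], hours[b] + group.bin_width / HOUR,
                               color="0.85", lw=0)
        ax.bar(hours, mean[d], width=group.bin_width / HOUR, align="edge",
               color="k")
        ax.set_ylim(0, top)
        ax.set_yticks([])
        ax.set_ylabel(f"d{d + 1}", rotation=0, ha="right", va="center")
    axes[-1].set_xlabel("clock time (h)")
    axes[-1].set_xlim(0, hours[-1] + group.bin_width / HOUR)
    fig.tight_layout()
    return fig


def group_overlay_figure(a: GroupActogram, b: GroupActogram, labels=("A", "B")):
    """Overlaid mean traces with SEM bands over the whole experiment."""
    fig, ax = plt.subplots(figsize=(10, 3))
    for grp, label, color in ((a, labels[0], "k"), (b, labels[1], "tab:blue")):
        y = grp.mean.ravel()
        s = grp.sem.ravel()
        x = np.arange(y.size) * grp.bin_width / HOUR
        ax.plot(x, y, color=color, label=f"{label} (n={grp.n_animals})")
        ax.fill_between(x, y - s, y + s, color=color, alpha=0.25, lw=0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("counts / bin")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
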