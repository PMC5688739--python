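import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from dopplercage.device import CHANNEL_COLUMNS, EventLog


def make_log(times_by_channel: dict[int, list], start="2024-01-01", light=0) -> EventLog:
    """Build an EventLog from per-channel second offsets (test helper)."""
    rows = []
    for ch, times in times_by_channel.items():
        for t in times:
            rows.append((pd.Timestamp(start) + pd.Timedelta(seconds=int(t)), ch))
    rows.sort(key=lambda r: r[0])
    frame = pd.DataFrame({"datetime": [r[0] for r in rows]})
    for i, col in enumerate(CHANNEL_COLUMNS, start=1):
        frame[col] = [1 if r[1] == i else 0 for r in rows]
    frame["light"] = light
    return EventLog(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
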