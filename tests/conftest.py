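import numpy as np
import pandas as pd
import pytest

from sowlying import AccelTrace, AnimalMeta, Ethogram

T0 = pd.Timestamp("2022-05-01 00:00:00")


def make_trace(y, start=T0, rate=1.0, gap_tolerance=5.0, animal_id="sow1",
               offsets=None):
    """AccelTrace from a y array at nominal rate, or at explicit second
    offsets from `start` (to punch coverage gaps)."""
    y = np.asarray(y, dtype=float)
    if offsets is None:
        offsets = np.arange(y.size) / rate
    time = pd.Timestamp(start).to_datetime64() + \
        (np.asarray(offsets, dtype=float) * 1e9).astype("timedelta64[ns]")
    return AccelTrace.from_arrays(animal_id, time, y, nominal_rate=rate,
                                  gap_tolerance=gap_tolerance)


def make_ethogram(events, animal_id="sow1", window=None):
    """Ethogram from (behavior, start_s, stop_s) offsets from midnight."""
    rows = [{"behavior": b,
             "start": T0 + pd.Timedelta(seconds=s),
             "stop": T0 + pd.Timedelta(seconds=e)} for b, s, e in events]
    if window is None:
        window = (T0, T0 + pd.Timedelta(days=2))
    return Ethogram(animal_id, pd.DataFrame(rows, columns=["behavior", "start", "stop"]),
                    window)


@pytest.fixture
def meta():
    return AnimalMeta("sow1", parturition_time=T0 + pd.Timedelta(hours=8))
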