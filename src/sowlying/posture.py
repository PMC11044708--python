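"""Per-sample lying classification and lying-bout extraction.

The classifier follows the leg-mounted accelerometer physics: the y-axis of
a standing sow reads about 1 g, a lying (or sitting) sow close to 0 g. A
sample is lying iff the moving-median-smoothed |y| falls strictly below the
critical lying value (default 0.75 g; values at exactly the threshold are
upright). The relatively high threshold accounts for sows not laying the
leg completely flat. |y| is used so an inverted logger mounting (y near
-1 g while standing) classifies identically.

Smoothing conventions (fixed, documented):

* Default window is 32 samples (32 s at 1 Hz), *centered*: 16 samples back,
  15 forward. The median of an even count is the mean of the two central
  order statistics.
* Smoothing is computed within contiguous coverage segments only, never
  across gaps. Where the nominal window does not fit at a segment edge it
  is truncated symmetrically to ``[i - m, i + m]`` with
  ``m = min(i, n - 1 - i)``.
* ``smooth="signal"`` (default) smooths |y| before thresholding;
  ``smooth="binary"`` thresholds first and takes a majority vote (moving
  median of the 0/1 labels, lying iff > 0.5) over the same window.
* A trailing window (``center=False``) is available; it covers
  ``[i - window + 1, i]`` truncated at the segment start.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AccelTrace, BoutTable, PostureSeries
from .errors import ParameterError, ValidationError


def moving_median(values, window: int = 32, center: bool = True) -> np.ndarray:
    """Moving median of a contiguous 1-D signal under the package's window
    conventions (see module docstring)."""
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    n = v.size
    if n == 0:
        return v.copy()
    if not center:
        return pd.Series(v).rolling(window, min_periods=1).median().to_numpy()

    back = window // 2
    fwd = window - back - 1
    out = np.empty(n, dtype=float)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(v, window)
        out[back:n - fwd] = np.median(sw, axis=1)
        edges = list(range(back)) + list(range(n - fwd, n))
    else:
        edges = range(n)
    for i in edges:
        m = min(i, n - 1 - i)
        out[i] = np.median(v[i - m:i + m + 1])
    return out


def classify_samples(trace: AccelTrace, critical_value: float = 0.75,
                     window: int = 32, smooth: str = "signal",
                     center: bool = True) -> PostureSeries:
    """Classify every sample of a trace as lying vs upright.

    Parameters
    ----------
    critical_value : float
        Critical lying value in g; lying iff smoothed |y| < critical_value.
    window : int
        Moving-median window in samples.
    smooth : {"signal", "binary"}
        Smooth the |y| signal before thresholding, or majority-vote the
        per-sample binary labels over the same window.
    """
    if critical_value <= 0:
        raise ParameterError(f"critical_value must be > 0, got {critical_value}")
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if smooth not in ("signal", "binary"):
        raise ParameterError(f"smooth must be 'signal' or 'binary', got {smooth!r}")
    if trace.n_samples == 0:
        raise ValidationError("cannot classify an empty trace")

    a = np.abs(trace.y)
    lying = np.zeros(trace.n_samples, dtype=bool)
    for seg in trace.segments:
        if smooth == "signal":
            sm = moving_median(a[seg], window=window, center=center)
            lying[seg] = sm < critical_value
        else:
            labels = (a[seg] < critical_value).astype(float)
            sm = moving_median(labels, window=window, center=center)
            lying[seg] = sm > 0.5
    return PostureSeries(
        animal_id=trace.animal_id, time=trace.time, lying=lying,
        segments=list(trace.segments), nominal_rate=trace.nominal_rate,
        params={"critical_value": critical_value, "window": window,
                "smooth": smooth, "center": center})


def extract_bouts(series: PostureSeries) -> BoutTable:
    """Turn maximal runs of lying samples into a bout table.

    A bout starts at its first lying sample and stops at the first
    subsequent non-lying sample (or, at a segment end, one nominal period
    after the last sample, so each sample contributes exactly 1/rate
    seconds). Runs abutting a segment boundary — the trace edge or a
    coverage gap — are flagged truncated on that side; bouts never span
    gaps.
    """
    period = pd.Timedelta(seconds=1.0 / series.nominal_rate)
    records = []
    for seg in series.segments:
        lying = series.lying[seg]
        t = series.time[seg]
        n = lying.size
        if n == 0:
            continue
        padded = np.concatenate(([False], lying, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        stops = np.flatnonzero(padded[:-1] & ~padded[1:])  # first index after run
        for i0, i1 in zip(starts, stops):
            at_end = i1 == n
            stop = pd.Timestamp(t[n - 1]) + period if at_end else pd.Timestamp(t[i1])
            records.append({
                "behavior": "lying",
                "start": pd.Timestamp(t[i0]),
                "stop": stop,
                "truncated_start": bool(i0 == 0),
                "truncated_end": bool(at_end),
            })
    return BoutTable.from_records(series.animal_id, records, source="sensor")
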