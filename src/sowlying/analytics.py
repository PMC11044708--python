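"""Parturition-aligned quarter-day summaries of lying behaviour.

Each calendar day is segmented into four 6-h wall-clock quarters —
late_night 00:00-06:00, morning 06:00-12:00, afternoon 12:00-18:00 and
early_night 18:00-24:00 — and indexed by the day relative to parturition
(day 0 = the calendar day of parturition). The quarter bounds are
configurable; the defaults encode the conventional mapping of the named
periods onto the clock.

Counting rules (fixed, documented):

* ``lying_s`` of a quarter is the summed intersection of lying bouts with
  the quarter window, so quarter durations add up exactly to daily totals.
* ``n_bouts`` attributes each bout to the quarter containing its *start*
  timestamp only, so a bout spanning midnight is counted once and daily
  bout sums stay consistent.
* ``coverage_s`` is the observed (non-gap) sensor time in the quarter;
  quarters with zero coverage yield no row.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .core import AnimalMeta, BoutTable, intervals_overlap_seconds
from .errors import ConfigError

#: quarter name -> (start hour, stop hour), half-open on the clock
DEFAULT_QUARTERS = {
    "late_night": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 18),
    "early_night": (18, 24),
}

QUARTER_ORDER = list(DEFAULT_QUARTERS)


def day_relative(t, parturition_time) -> int:
    """Calendar-day difference between ``t`` and the parturition day.

    Wall-clock dates, not 24-h offsets: any time on the parturition date is
    day 0, the next calendar date is day +1.
    """
    t = pd.Timestamp(t)
    p = pd.Timestamp(parturition_time)
    return (t.normalize() - p.normalize()).days


def quarter_windows(day: dt.date, quarters=None):
    """Yield (name, start, stop) wall-clock windows for one calendar day."""
    quarters = quarters or DEFAULT_QUARTERS
    midnight = pd.Timestamp(day)
    for name, (h0, h1) in quarters.items():
        yield name, midnight + pd.Timedelta(hours=h0), midnight + pd.Timedelta(hours=h1)


def summarize_quarters(bouts: BoutTable, coverage, meta: AnimalMeta,
                       quarters=None) -> pd.DataFrame:
    """Summarize lying behaviour per day-relative-to-parturition x quarter.

    Parameters
    ----------
    bouts : BoutTable
        Non-overlapping lying/rest bouts for one animal.
    coverage : list of (start, stop)
        Half-open intervals of valid observation (sensor coverage or the
        video observation window); gaps are excluded from denominators.
    meta : AnimalMeta
        Must carry ``parturition_time``; day 0 is its calendar date.

    Returns
    -------
    DataFrame with columns animal_id, day_rel, quarter, n_bouts, lying_s,
    coverage_s, proportion — one row per quarter with coverage_s > 0.
    """
    if meta.parturition_time is None or pd.isna(meta.parturition_time):
        raise ConfigError(
            f"animal {meta.animal_id!r}: parturition_time is required "
            "for parturition-aligned summaries")
    coverage = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in coverage]
    rows = []
    if coverage:
        first = min(s for s, _ in coverage).normalize()
        # stop is exclusive: coverage ending exactly at midnight adds no day
        last = max(e - pd.Timedelta(nanoseconds=1) for _, e in coverage).normalize()
        for day in pd.date_range(first, last, freq="D"):
            for name, w0, w1 in quarter_windows(day.date(), quarters):
                cov = intervals_overlap_seconds(coverage, w0, w1)
                if cov <= 0:
                    continue
                lying = bouts.seconds_in(w0, w1)
                n = bouts.count_starting_in(w0, w1)
                rows.append({
                    "animal_id": meta.animal_id,
                    "day_rel": day_relative(w0, meta.parturition_time),
                    "quarter": name,
                    "n_bouts": n,
                    "lying_s": lying,
                    "coverage_s": cov,
                    "proportion": lying / cov,
                })
    return pd.DataFrame(rows, columns=["animal_id", "day_rel", "quarter",
                                       "n_bouts", "lying_s", "coverage_s",
                                       "proportion"])
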