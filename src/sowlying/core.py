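"""Core in-memory containers for the sow lying-behaviour pipeline.

Time conventions used throughout the package:

* Timestamps are timezone-naive wall-clock times (``pandas.Timestamp``).
  Day quarters are barn-local clock periods, so no zone conversion is ever
  performed.
* Every bout/event interval is half-open, ``[start, stop)``: adjacency is
  legal, overlap is not, and durations are additive.
* Each accelerometer sample at time ``t`` represents the interval
  ``[t, t + 1/rate)``; a *coverage gap* is an inter-sample interval larger
  than ``gap_tolerance`` and carries no posture state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("sowlying")

BEHAVIORS = frozenset({"lying", "sitting"})

#: canonical column order of a bout table on disk
BOUT_COLUMNS = ["animal_id", "behavior", "start", "stop", "duration_s",
                "truncated_start", "truncated_end"]


def overlap_seconds(a_start, a_stop, b_start, b_stop) -> float:
    """Length in seconds of the intersection of two half-open intervals."""
    lo = max(a_start, b_start)
    hi = min(a_stop, b_stop)
    if hi <= lo:
        return 0.0
    return (hi - lo).total_seconds()


def intervals_overlap_seconds(intervals, win_start, win_stop) -> float:
    """Summed intersection of a list of half-open intervals with a window."""
    return sum(overlap_seconds(s, e, win_start, win_stop) for s, e in intervals)


@dataclass
class AccelTrace:
    """Timestamped y-axis (optionally x, z) acceleration series for one animal.

    The y-axis is the logger axis parallel to the leg: a standing sow reads
    about 1 g of static gravitational acceleration on it, a lying (or
    sitting) sow close to 0 g, because the tarsus is then roughly parallel
    to the ground.

    Attributes
    ----------
    time : np.ndarray of datetime64[ns]
        Strictly increasing sample timestamps.
    y : np.ndarray of float
        Acceleration in g; all retained samples are finite.
    gaps : list of (Timestamp, Timestamp)
        Uncovered intervals: wherever the inter-sample interval exceeds
        ``gap_tolerance``, the gap (last sample before + one nominal
        period, first sample after) is recorded.
    segments : list of slice
        Maximal runs of samples uninterrupted by a coverage gap.
    """

    animal_id: str
    time: np.ndarray
    y: np.ndarray
    x: np.ndarray | None = None
    z: np.ndarray | None = None
    nominal_rate: float = 1.0
    gap_tolerance: float = 5.0
    gaps: list = field(default_factory=list)
    segments: list = field(default_factory=list)

    @classmethod
    def from_arrays(cls, animal_id: str, time, y, x=None, z=None,
                    nominal_rate: float = 1.0,
                    gap_tolerance: float = 5.0) -> "AccelTrace":
        """Build a validated trace: drop non-finite samples, collapse
        duplicate timestamps (keeping the first), and index coverage gaps."""
        time = pd.DatetimeIndex(time).to_numpy(dtype="datetime64[ns]")
        y = np.asarray(y, dtype=float)
        optional = {"x": x, "z": z}
        optional = {k: (np.asarray(v, dtype=float) if v is not None else None)
                    for k, v in optional.items()}
        if time.shape != y.shape:
            raise ValidationError("time and y must have equal length")

        keep = np.isfinite(y)
        n_bad = int((~keep).sum())
        if n_bad:
            logger.warning("%s: dropped %d non-finite y samples", animal_id, n_bad)

        order = np.argsort(time, kind="stable")
        time, y = time[order][keep[order]], y[order][keep[order]]
        optional = {k: (v[order][keep[order]] if v is not None else None)
                    for k, v in optional.items()}

        if time.size:
            uniq = np.concatenate(([True], np.diff(time).astype("int64") > 0))
            n_dup = int((~uniq).sum())
            if n_dup:
                logger.warning("%s: collapsed %d duplicate timestamps "
                               "(first occurrence kept)", animal_id, n_dup)
                time, y = time[uniq], y[uniq]
                optional = {k: (v[uniq] if v is not None else None)
                            for k, v in optional.items()}

        trace = cls(animal_id=animal_id, time=time, y=y,
                    x=optional["x"], z=optional["z"],
                    nominal_rate=nominal_rate, gap_tolerance=gap_tolerance)
        trace._index_gaps()
        return trace

    def _index_gaps(self) -> None:
        self.gaps = []
        self.segments = []
        n = self.time.size
        if n == 0:
            return
        dt = np.diff(self.time) / np.timedelta64(1, "s")
        breaks = np.flatnonzero(dt > self.gap_tolerance)
        start = 0
        for b in breaks:
            self.segments.append(slice(start, b + 1))
            self.gaps.append((pd.Timestamp(self.time[b]) + self.period,
                              pd.Timestamp(self.time[b + 1])))
            start = b + 1
        self.segments.append(slice(start, n))

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def period(self) -> pd.Timedelta:
        return pd.Timedelta(seconds=1.0 / self.nominal_rate)

    def coverage_intervals(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Half-open intervals of valid coverage, one per contiguous segment.

        Each sample covers one nominal period, so a segment covers
        ``[first sample, last sample + 1/rate)``.
        """
        out = []
        for seg in self.segments:
            first = pd.Timestamp(self.time[seg.start])
            last = pd.Timestamp(self.time[seg.stop - 1])
            out.append((first, last + self.period))
        return out


@dataclass
class Ethogram:
    """Observer-coded behaviour bouts (lying / sitting) for one animal.

    Time not covered by any event is implicitly upright/standing. Events are
    validated to be ordered, non-overlapping half-open intervals inside the
    observation window.
    """

    animal_id: str
    events: pd.DataFrame
    observation_window: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self):
        ev = self.events.copy()
        if ev.empty:
            ev = pd.DataFrame(columns=["behavior", "start", "stop"])
        ev["start"] = pd.to_datetime(ev["start"])
        ev["stop"] = pd.to_datetime(ev["stop"])
        ev = ev.sort_values(["start", "stop"], kind="stable").reset_index(drop=True)

        bad_beh = set(ev["behavior"]) - BEHAVIORS
        if bad_beh:
            raise ValidationError(f"unknown behaviors: {sorted(bad_beh)}")
        bad = ev[ev["stop"] <= ev["start"]]
        if len(bad):
            raise ValidationError(
                f"event with stop <= start: {bad.iloc[0].to_dict()}")
        if len(ev) > 1:
            overlap = ev["start"].iloc[1:].to_numpy() < ev["stop"].iloc[:-1].to_numpy()
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                raise ValidationError(
                    "overlapping events: "
                    f"{ev.iloc[i].to_dict()} and {ev.iloc[i + 1].to_dict()}")
        w0, w1 = self.observation_window
        w0, w1 = pd.Timestamp(w0), pd.Timestamp(w1)
        if len(ev) and (ev["start"].min() < w0 or ev["stop"].max() > w1):
            raise ValidationError("events extend beyond the observation window")
        self.observation_window = (w0, w1)
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class AnimalMeta:
    """Per-animal metadata needed for parturition-aligned summaries."""

    animal_id: str
    parturition_time: pd.Timestamp
    housing: str = "crate"        # {crate, free}
    parity_class: str = "multiparous"  # {gilt, multiparous}
    batch: str = ""

    def __post_init__(self):
        if self.parturition_time is not None and not pd.isna(self.parturition_time):
            self.parturition_time = pd.Timestamp(self.parturition_time)


@dataclass
class PostureSeries:
    """Per-sample lying / upright classification of an accelerometer trace.

    Carries the segment structure of its source trace: samples in a coverage
    gap have no state, and downstream bout extraction never bridges a gap.
    """

    animal_id: str
    time: np.ndarray
    lying: np.ndarray
    segments: list
    nominal_rate: float
    params: dict = field(default_factory=dict)

    @property
    def n_lying(self) -> int:
        return int(self.lying.sum())


@dataclass
class BoutTable:
    """Non-overlapping behaviour bouts as half-open intervals.

    ``source`` records provenance: "sensor" (classifier), "ethogram"
    (video lying bouts as coded) or "ethogram_merged" (rest bouts with
    transitional sitting absorbed).
    """

    animal_id: str
    bouts: pd.DataFrame
    source: str = "sensor"

    _COLS = ["behavior", "start", "stop", "duration_s",
             "truncated_start", "truncated_end"]

    def __post_init__(self):
        b = self.bouts.copy()
        if b.empty:
            b = pd.DataFrame(columns=self._COLS)
        for col in ("truncated_start", "truncated_end"):
            if col not in b.columns:
                b[col] = False
        b["start"] = pd.to_datetime(b["start"])
        b["stop"] = pd.to_datetime(b["stop"])
        if "duration_s" not in b.columns or b["duration_s"].isna().any():
            b["duration_s"] = (b["stop"] - b["start"]).dt.total_seconds()
        b["duration_s"] = b["duration_s"].astype(float)
        b["truncated_start"] = b["truncated_start"].astype(bool)
        b["truncated_end"] = b["truncated_end"].astype(bool)
        b = b[self._COLS].sort_values(["start", "stop"], kind="stable")
        b = b.reset_index(drop=True)

        if len(b):
            if (b["stop"] <= b["start"]).any():
                raise ValidationError("bout with stop <= start")
            span = (b["stop"] - b["start"]).dt.total_seconds()
            if not np.allclose(span, b["duration_s"], rtol=0, atol=0):
                raise ValidationError("duration_s does not equal stop - start")
        if len(b) > 1:
            overlap = b["start"].iloc[1:].to_numpy() < b["stop"].iloc[:-1].to_numpy()
            if overlap.any():
                raise ValidationError("overlapping bouts")
        self.bouts = b

    @classmethod
    def empty(cls, animal_id: str, source: str = "sensor") -> "BoutTable":
        return cls(animal_id, pd.DataFrame(columns=cls._COLS), source)

    @classmethod
    def from_records(cls, animal_id: str, records: Iterable[dict],
                     source: str = "sensor") -> "BoutTable":
        return cls(animal_id, pd.DataFrame(list(records)), source)

    @classmethod
    def from_ethogram(cls, eth: Ethogram,
                      behaviors: Sequence[str] = ("lying",)) -> "BoutTable":
        """Lift the selected ethogram events verbatim into a bout table
        (sitting interrupts lying, exactly as coded on video)."""
        ev = eth.events[eth.events["behavior"].isin(behaviors)]
        recs = [{"behavior": r.behavior, "start": r.start, "stop": r.stop}
                for r in ev.itertuples()]
        return cls.from_records(eth.animal_id, recs, source="ethogram")

    def __len__(self) -> int:
        return len(self.bouts)

    def total_seconds(self) -> float:
        return float(self.bouts["duration_s"].sum())

    def intervals(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        return list(zip(self.bouts["start"], self.bouts["stop"]))

    def seconds_in(self, win_start, win_stop) -> float:
        """Summed bout time intersecting the half-open window."""
        return intervals_overlap_seconds(self.intervals(), win_start, win_stop)

    def count_starting_in(self, win_start, win_stop) -> int:
        """Number of bouts whose start timestamp falls in the window.

        Start-attribution is the bout-counting rule everywhere in the
        package: a bout spanning a window boundary is counted once, in the
        window that contains its start.
        """
        s = self.bouts["start"]
        return int(((s >= win_start) & (s < win_stop)).sum())
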