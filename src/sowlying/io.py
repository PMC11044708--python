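"""Readers and writers for the pipeline's tabular artifacts.

All files are delimited text. Timestamps are written as
``YYYY-MM-DD HH:MM:SS`` (ISO-8601 with a space separator) and parsed
locale-independently; decimal values always use a decimal point. Bout and
summary tables round-trip losslessly through the matching reader for every
value representable at the declared precision.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AccelTrace, AnimalMeta, BoutTable, Ethogram
from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger("sowlying")

DEFAULT_ACCEL_COLUMNS = {"time": "time", "x": "x", "y": "y", "z": "z"}
DEFAULT_ETHOGRAM_COLUMNS = {"behavior": "behavior", "start": "start", "stop": "stop"}

SUMMARY_COLUMNS = ["animal_id", "day_rel", "quarter", "n_bouts",
                   "lying_s", "coverage_s", "proportion"]


def _parse_timestamps(raw: pd.Series, path, colname: str) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: unparseable timestamp {raw[bad].iloc[0]!r} "
            f"in column {colname!r} at line {line}")
    if parsed.isna().any():
        line = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: missing timestamp at line {line}")
    return parsed


def read_accel_csv(path, column_map=None, gap_tolerance: float = 5.0,
                   animal_id: str | None = None, nominal_rate: float = 1.0,
                   delimiter: str = ",") -> AccelTrace:
    """Read a logger-style CSV into an :class:`AccelTrace`.

    Parameters
    ----------
    column_map : dict, optional
        Maps the logical names ``time`` and ``y`` (``x``, ``z`` optional) to
        the column headers in the file. Defaults to the plain
        (time, x, y, z) layout; unknown extra columns are ignored.
    gap_tolerance : float
        Inter-sample intervals longer than this many seconds are recorded
        as coverage gaps.
    """
    cmap = dict(DEFAULT_ACCEL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter)
    if cmap["time"] not in df.columns:
        raise ConfigError(f"{path}: no timestamp column {cmap['time']!r}")
    if cmap["y"] not in df.columns:
        raise ConfigError(f"{path}: no y-axis column {cmap['y']!r}")
    time = _parse_timestamps(df[cmap["time"]], path, cmap["time"])
    kw = {}
    for axis in ("x", "z"):
        col = cmap.get(axis)
        if col is not None and col in df.columns:
            kw[axis] = df[col].to_numpy(dtype=float)
    if animal_id is None:
        animal_id = str(path)
    return AccelTrace.from_arrays(animal_id, time, df[cmap["y"]].to_numpy(dtype=float),
                                  nominal_rate=nominal_rate,
                                  gap_tolerance=gap_tolerance, **kw)


def read_ethogram_csv(path, column_map=None, animal_id: str | None = None,
                      observation_window=None, dialect: str = "interval",
                      delimiter: str = ",") -> Ethogram:
    """Read an observer-coded ethogram (BORIS-style tabular export).

    Two dialects are supported:

    * ``interval`` (default): one row per bout with behavior / start / stop
      columns.
    * ``events``: paired state-event rows with behavior / time / status
      columns, where status is START or STOP (case-insensitive); each START
      is closed by the next STOP of the same behavior.
    """
    df = pd.read_csv(path, sep=delimiter)
    if dialect == "interval":
        cmap = dict(DEFAULT_ETHOGRAM_COLUMNS)
        if column_map:
            cmap.update(column_map)
        for key in ("behavior", "start", "stop"):
            if cmap[key] not in df.columns:
                raise ConfigError(f"{path}: no {key} column {cmap[key]!r}")
        events = pd.DataFrame({
            "behavior": df[cmap["behavior"]].astype(str).str.lower(),
            "start": _parse_timestamps(df[cmap["start"]], path, cmap["start"]),
            "stop": _parse_timestamps(df[cmap["stop"]], path, cmap["stop"]),
        })
    elif dialect == "events":
        cmap = {"behavior": "behavior", "time": "time", "status": "status"}
        if column_map:
            cmap.update(column_map)
        for key in cmap:
            if cmap[key] not in df.columns:
                raise ConfigError(f"{path}: no {key} column {cmap[key]!r}")
        t = _parse_timestamps(df[cmap["time"]], path, cmap["time"])
        status = df[cmap["status"]].astype(str).str.upper()
        beh = df[cmap["behavior"]].astype(str).str.lower()
        open_events: dict[str, pd.Timestamp] = {}
        rows = []
        for b, ts, st in sorted(zip(beh, t, status), key=lambda r: r[1]):
            if st == "START":
                if b in open_events:
                    raise ValidationError(
                        f"{path}: START of {b!r} at {ts} while already open")
                open_events[b] = ts
            elif st == "STOP":
                if b not in open_events:
                    raise ValidationError(
                        f"{path}: STOP of {b!r} at {ts} without START")
                rows.append({"behavior": b, "start": open_events.pop(b), "stop": ts})
            else:
                raise FormatError(f"{path}: unknown status {st!r}")
        if open_events:
            raise ValidationError(f"{path}: unterminated events {open_events}")
        events = pd.DataFrame(rows, columns=["behavior", "start", "stop"])
    else:
        raise ConfigError(f"unknown ethogram dialect {dialect!r}")

    if animal_id is None:
        animal_id = str(path)
    if observation_window is None:
        if events.empty:
            raise ConfigError(
                f"{path}: empty ethogram needs an explicit observation_window")
        observation_window = (events["start"].min(), events["stop"].max())
    return Ethogram(animal_id, events, observation_window)


def read_meta_csv(path, delimiter: str = ",") -> dict[str, AnimalMeta]:
    """Read animal metadata (animal_id, parturition_time, housing,
    parity_class, batch) into a dict keyed by animal id."""
    df = pd.read_csv(path, sep=delimiter)
    for col in ("animal_id", "parturition_time"):
        if col not in df.columns:
            raise ConfigError(f"{path}: no column {col!r}")
    out = {}
    for r in df.itertuples():
        part = pd.to_datetime(r.parturition_time, errors="coerce")
        out[str(r.animal_id)] = AnimalMeta(
            animal_id=str(r.animal_id),
            parturition_time=part,
            housing=str(getattr(r, "housing", "crate")),
            parity_class=str(getattr(r, "parity_class", "multiparous")),
            batch=str(getattr(r, "batch", "")),
        )
    return out


def _format_times(df: pd.DataFrame, cols) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        df[c] = pd.to_datetime(df[c]).map(
            lambda t: t.isoformat(sep=" "))
    return df


def write_bouts(bouts: BoutTable, path) -> None:
    """Write a bout table as CSV with the documented column order
    (animal_id, behavior, start, stop, duration_s, truncated_start,
    truncated_end)."""
    df = bouts.bouts.copy()
    df.insert(0, "animal_id", bouts.animal_id)
    df = _format_times(df, ["start", "stop"])
    df.to_csv(path, index=False)


def read_bouts(path, source: str = "sensor", delimiter: str = ",") -> BoutTable:
    """Read a bout table written by :func:`write_bouts`."""
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        return BoutTable.empty("", source=source)
    ids = df["animal_id"].astype(str).unique()
    if len(ids) != 1:
        raise ValidationError(f"{path}: expected one animal_id, found {list(ids)}")
    df = df.drop(columns=["animal_id"])
    df["start"] = _parse_timestamps(df["start"], path, "start")
    df["stop"] = _parse_timestamps(df["stop"], path, "stop")
    return BoutTable(str(ids[0]), df, source=source)


def write_summaries(summaries: pd.DataFrame, path) -> None:
    """Write a quarter-summary table (animal_id, day_rel, quarter, n_bouts,
    lying_s, coverage_s, proportion) as CSV."""
    summaries[SUMMARY_COLUMNS].to_csv(path, index=False)


def read_summaries(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing summary columns {sorted(missing)}")
    df["animal_id"] = df["animal_id"].astype(str)
    df["day_rel"] = df["day_rel"].astype(int)
    df["n_bouts"] = df["n_bouts"].astype(int)
    for c in ("lying_s", "coverage_s", "proportion"):
        df[c] = df[c].astype(float)
    return df[SUMMARY_COLUMNS]
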