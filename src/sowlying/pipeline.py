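"""End-to-end orchestration: simulate -> classify -> summarize -> validate.

A :class:`RunConfig` fixes every parameter of a run (classifier settings,
quarter bounds, ICC form, seed); :func:`run_pipeline` executes the stages
and writes a machine-readable manifest so that any run is reproducible from
its manifest alone. The manifest deliberately records no wall-clock time:
identical config + seed must produce bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement import build_ratings, icc_agreement, merge_transitional_sitting
from .analytics import DEFAULT_QUARTERS, summarize_quarters
from .core import AnimalMeta, BoutTable, Ethogram
from .errors import ConfigError
from .ethosim import SensorModel, preset, render_accel, simulate_ethogram
from .io import (read_accel_csv, read_ethogram_csv, read_meta_csv,
                 write_bouts, write_summaries)
from .posture import classify_samples, extract_bouts


@dataclass
class RunConfig:
    """Parameters of one pipeline run. Defaults mirror the study setup:
    1 Hz sampling, critical lying value 0.75 g, window 32 samples, quarters
    at 00/06/12/18, day 0 = parturition date."""

    out_dir: str = "run"
    # input mode A: files
    accel_path: str | None = None
    video_path: str | None = None
    meta_path: str | None = None
    animal_id: str | None = None
    # input mode B: simulation
    simulate_preset: str | None = None
    simulate_days: list | None = None  # subset of the preset's day range
    parturition_time: str = "2022-05-15 08:00:00"
    # classifier
    critical_value: float = 0.75
    window: int = 32
    smooth: str = "signal"
    center: bool = True
    gap_tolerance: float = 5.0
    # analytics / agreement
    quarters: dict = field(default_factory=lambda: dict(DEFAULT_QUARTERS))
    icc_form: str = "A,1"
    adjacency_tolerance: float = 1.0
    min_coverage_fraction: float = 0.75
    measure: str = "bout_count"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def day_windows(coverage, animal_id: str):
    """One 24-h rating window per calendar day touched by coverage."""
    if not coverage:
        return []
    first = min(s for s, _ in coverage).normalize()
    last = max(e - pd.Timedelta(nanoseconds=1) for _, e in coverage).normalize()
    windows = []
    for day in pd.date_range(first, last, freq="D"):
        windows.append((f"{animal_id}:{day.date().isoformat()}",
                        day, day + pd.Timedelta(days=1)))
    return windows


def validate_agreement(video: Ethogram, sensor_bouts: BoutTable, coverage,
                       measure: str = "bout_count", merge_sitting: bool = True,
                       icc_form: str = "A,1", adjacency_tolerance: float = 1.0,
                       min_coverage_fraction: float = 0.75) -> dict:
    """ICC agreement report between a video ethogram and sensor bouts."""
    if merge_sitting:
        video_bouts = merge_transitional_sitting(
            video, adjacency_tolerance=adjacency_tolerance)
    else:
        video_bouts = BoutTable.from_ethogram(video)
    windows = day_windows(coverage, video.animal_id)
    ratings = build_ratings(video_bouts, sensor_bouts, windows, measure=measure,
                            sensor_coverage=coverage,
                            min_coverage_fraction=min_coverage_fraction)
    res = icc_agreement(ratings, form=icc_form)
    return {
        "measure": measure,
        "merge_sitting": merge_sitting,
        "icc_form": icc_form,
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "n_subjects": res.n,
        "n_windows_total": len(windows),
        "n_windows_dropped": len(windows) - res.n,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and return the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    artifacts: dict[str, str] = {}

    video_eth: Ethogram | None = None
    if config.simulate_preset is not None:
        scenario = preset(config.simulate_preset, seed=config.seed)
        if config.simulate_days is not None:
            scenario = dataclasses.replace(
                scenario, days=tuple(config.simulate_days))
        eth, truth = simulate_ethogram(scenario, config.parturition_time,
                                       animal_id=config.animal_id)
        trace = render_accel(eth, SensorModel(), seed=config.seed + 1)
        video_eth = eth
        meta = AnimalMeta(animal_id=eth.animal_id,
                          parturition_time=pd.Timestamp(config.parturition_time),
                          housing=scenario.housing)
        eth_path = out / "ethogram.csv"
        eth.events.assign(animal_id=eth.animal_id).to_csv(eth_path, index=False)
        write_bouts(truth, out / "truth_bouts.csv")
        accel_path = out / "accel.csv"
        pd.DataFrame({"time": pd.DatetimeIndex(trace.time).map(
            lambda t: t.isoformat(sep=" ")), "y": trace.y}
        ).to_csv(accel_path, index=False)
        artifacts["ethogram.csv"] = _sha256(eth_path)
        artifacts["truth_bouts.csv"] = _sha256(out / "truth_bouts.csv")
        artifacts["accel.csv"] = _sha256(accel_path)
    else:
        if config.accel_path is None:
            raise ConfigError("need either accel_path or simulate_preset")
        trace = read_accel_csv(config.accel_path,
                               gap_tolerance=config.gap_tolerance,
                               animal_id=config.animal_id)
        inputs[str(config.accel_path)] = _sha256(Path(config.accel_path))
        if config.meta_path is None:
            raise ConfigError("meta_path with parturition_time is required")
        metas = read_meta_csv(config.meta_path)
        inputs[str(config.meta_path)] = _sha256(Path(config.meta_path))
        if trace.animal_id not in metas:
            raise ConfigError(f"animal {trace.animal_id!r} missing from "
                              f"{config.meta_path}")
        meta = metas[trace.animal_id]
        if config.video_path is not None:
            video_eth = read_ethogram_csv(config.video_path,
                                          animal_id=trace.animal_id)
            inputs[str(config.video_path)] = _sha256(Path(config.video_path))

    series = classify_samples(trace, critical_value=config.critical_value,
                              window=config.window, smooth=config.smooth,
                              center=config.center)
    bouts = extract_bouts(series)
    write_bouts(bouts, out / "bouts.csv")
    artifacts["bouts.csv"] = _sha256(out / "bouts.csv")

    coverage = trace.coverage_intervals()
    summaries = summarize_quarters(bouts, coverage, meta,
                                   quarters=config.quarters)
    write_summaries(summaries, out / "quarters.csv")
    artifacts["quarters.csv"] = _sha256(out / "quarters.csv")

    if video_eth is not None:
        report = {
            "raw": validate_agreement(
                video_eth, bouts, coverage, measure=config.measure,
                merge_sitting=False, icc_form=config.icc_form,
                adjacency_tolerance=config.adjacency_tolerance,
                min_coverage_fraction=config.min_coverage_fraction),
            "merged": validate_agreement(
                video_eth, bouts, coverage, measure=config.measure,
                merge_sitting=True, icc_form=config.icc_form,
                adjacency_tolerance=config.adjacency_tolerance,
                min_coverage_fraction=config.min_coverage_fraction),
        }
        (out / "icc.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        artifacts["icc.json"] = _sha256(out / "icc.json")

    config_dict = config.to_dict()
    config_dict.pop("out_dir")  # where the manifest lives, not what it means
    manifest = {
        "sowlying_version": __version__,
        "config": config_dict,
        "inputs": inputs,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
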