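"""Synthetic ethograms and accelerometer traces for desk-scale testing.

The generator emulates the structure the analysis assumes, without claiming
to reproduce any field dataset:

* Behaviour is an alternating upright/rest renewal process per 6-h quarter.
  Given a quarter's target lying proportion ``p`` and target rest-bout rate
  ``r`` (bouts per 6 h), episode durations are exponential with

      mean rest duration    = p * 21600 / r
      mean upright duration = (1 - p) * 21600 / r

  truncated at quarter boundaries; adjacent same-state episodes across a
  boundary coalesce, so a sow lying over midnight is one ground-truth rest
  bout. Durations are floored at short minima (a sow neither stands nor
  rests for mere seconds) and rounded to whole seconds to match 1 Hz
  sampling.
* Each rest episode is decomposed into lying sub-bouts separated or flanked
  by brief *transitional sitting* — the posture a sow passes through before
  lying down, after rising, or between lying bouts — which a hind-leg
  sensor cannot distinguish from lying.
* The sensor model renders leg-angle physics: the y-axis reads
  cos(leg angle from vertical) g, about 1 g standing (angle near 0°) and
  about 0 g lying or sitting (angle near 90°), plus Gaussian sample noise
  and high-variance bursts around posture transitions.

Presets encode the qualitative day-courses around parturition reported for
farrowing-crate and free-farrowing sows (nest-building bout peak, post-
parturition trough, nest-leaving rise; near-total lying 18:00-24:00); they
are scenario fixtures, not empirical reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AccelTrace, BoutTable, Ethogram
from .errors import ConfigError

QUARTER_SECONDS = 21600
_QUARTER_HOURS = {"late_night": 0, "morning": 6, "afternoon": 12, "early_night": 18}

_MIN_LYING_PIECE_S = 10
_MIN_SITTING_S = 5


@dataclass
class SensorModel:
    """Leg-angle physics of the y-axis plus noise structure.

    Angles are degrees from vertical; the rendered baseline is
    cos(angle) g. Defaults: standing leg near-vertical (5 +/- 3 deg),
    lying and sitting tarsus near-horizontal (85 +/- 3 deg), 0.05 g sample
    noise, and 5-s 0.3 g bursts around posture changes (struggling to rise
    or flop down).
    """

    standing_angle_mean: float = 5.0
    standing_angle_sd: float = 3.0
    lying_angle_mean: float = 85.0
    lying_angle_sd: float = 3.0
    sitting_angle_mean: float = 85.0
    sitting_angle_sd: float = 3.0
    noise_sd: float = 0.05
    burst_duration_s: float = 5.0
    burst_sd: float = 0.3
    rate: float = 1.0

    def __post_init__(self):
        for name in ("standing", "lying", "sitting"):
            mean = getattr(self, f"{name}_angle_mean")
            sd = getattr(self, f"{name}_angle_sd")
            if not 0.0 <= mean <= 90.0:
                raise ConfigError(f"{name} angle mean must be in [0, 90] deg")
            if sd < 0:
                raise ConfigError(f"{name} angle sd must be >= 0")
        if self.noise_sd < 0 or self.burst_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        if self.rate <= 0:
            raise ConfigError("sampling rate must be > 0")


@dataclass
class ScenarioConfig:
    """Targets of the behaviour generator.

    ``proportion`` and ``rate`` map a quarter name (or ``"default"`` for
    all unnamed quarters) to piecewise-linear day-course anchors
    ``(days, values)``; values are the target lying proportion in [0, 1]
    and the target rest-bout rate in bouts per 6 h. ``sitting_prob`` is
    the probability a posture transition passes through sitting (and sets
    the intensity of interior sitting interruptions); sitting durations
    are normal(mean, sd) seconds, floored at 5 s.
    """

    housing: str = "crate"
    days: tuple = (0,)
    proportion: dict = field(default_factory=lambda: {"default": ((0,), (0.7,))})
    rate: dict = field(default_factory=lambda: {"default": ((0,), (2.0,))})
    sitting_prob: float = 0.3
    sitting_mean_s: float = 25.0
    sitting_sd_s: float = 10.0
    min_rest_s: float = 60.0
    min_upright_s: float = 30.0
    seed: int = 0

    def __post_init__(self):
        self.days = tuple(int(d) for d in self.days)
        if not self.days:
            raise ConfigError("days must be non-empty")
        for quarter, (_, values) in self.proportion.items():
            if not all(0.0 <= v <= 1.0 for v in values):
                raise ConfigError(f"proportions out of [0,1] for {quarter!r}")
        for quarter, (_, values) in self.rate.items():
            if not all(v >= 0.0 for v in values):
                raise ConfigError(f"negative rate for {quarter!r}")
        if not 0.0 <= self.sitting_prob <= 1.0:
            raise ConfigError("sitting_prob must be in [0,1]")
        if self.sitting_mean_s <= 0 or self.min_rest_s <= 0 or self.min_upright_s <= 0:
            raise ConfigError("durations must be positive")

    @classmethod
    def uniform(cls, proportion: float, rate: float, days=(0,), **kw) -> "ScenarioConfig":
        """Constant targets for every day and quarter (test scenarios)."""
        return cls(days=tuple(days),
                   proportion={"default": ((0,), (proportion,))},
                   rate={"default": ((0,), (rate,))}, **kw)

    def _interp(self, table: dict, day: int, quarter: str) -> float:
        anchors = table.get(quarter, table.get("default"))
        if anchors is None:
            raise ConfigError(f"no target for quarter {quarter!r}")
        xs, ys = anchors
        return float(np.interp(day, xs, ys))

    def target(self, day: int, quarter: str) -> tuple[float, float]:
        """(lying proportion, rest-bout rate per 6 h) for one quarter."""
        return (self._interp(self.proportion, day, quarter),
                self._interp(self.rate, day, quarter))


def _split_integer(rng, budget: int, m: int, minimum: int) -> list[int]:
    """Split an integer budget into m parts >= minimum with random weights."""
    extra = budget - m * minimum
    w = rng.dirichlet(np.ones(m))
    alloc = np.floor(w * extra).astype(int)
    rest = extra - int(alloc.sum())
    for i in range(rest):
        alloc[i % m] += 1
    return [minimum + int(a) for a in alloc]


def _decompose_rest(rng, dur: int, cfg: ScenarioConfig) -> list[tuple[str, int]]:
    """Split one rest episode into a lying/sitting sub-event sequence whose
    durations sum exactly to the episode duration."""
    if cfg.sitting_prob <= 0 or dur < 2 * _MIN_LYING_PIECE_S + _MIN_SITTING_S:
        return [("lying", dur)]

    def draw_sit() -> int:
        d = rng.normal(cfg.sitting_mean_s, cfg.sitting_sd_s)
        return max(_MIN_SITTING_S, int(round(d)))

    sit_entry = draw_sit() if rng.random() < cfg.sitting_prob else 0
    sit_exit = draw_sit() if rng.random() < cfg.sitting_prob else 0
    # interior interruptions: on average sitting_prob per 30 min of rest
    k = int(rng.poisson(cfg.sitting_prob * dur / 1800.0))
    interior = [draw_sit() for _ in range(k)]

    while True:
        k = len(interior)
        lying_budget = dur - sit_entry - sit_exit - sum(interior)
        if lying_budget >= (k + 1) * _MIN_LYING_PIECE_S:
            break
        if interior:
            interior.pop()
        elif sit_exit:
            sit_exit = 0
        elif sit_entry:
            sit_entry = 0
        else:
            return [("lying", dur)]

    pieces = _split_integer(rng, lying_budget, k + 1, _MIN_LYING_PIECE_S)
    seq: list[tuple[str, int]] = []
    if sit_entry:
        seq.append(("sitting", sit_entry))
    for i, ly in enumerate(pieces):
        if i:
            seq.append(("sitting", interior[i - 1]))
        seq.append(("lying", ly))
    if sit_exit:
        seq.append(("sitting", sit_exit))
    return seq


def _quarter_episodes(rng, p: float, r: float, cfg: ScenarioConfig):
    """Alternating upright/rest episodes for one 6-h quarter, as
    (is_rest, duration) pairs summing to QUARTER_SECONDS."""
    if r == 0:
        if p == 0.0:
            return [(False, QUARTER_SECONDS)]
        if p == 1.0:
            return [(True, QUARTER_SECONDS)]
        raise ConfigError(
            f"rate 0 cannot realize proportion {p} strictly inside (0, 1)")
    if p <= 0.0:
        return [(False, QUARTER_SECONDS)]
    if p >= 1.0:
        return [(True, QUARTER_SECONDS)]
    mean_rest = p * QUARTER_SECONDS / r
    mean_up = (1.0 - p) * QUARTER_SECONDS / r
    episodes = []
    rest = bool(rng.random() < p)
    t = 0
    while t < QUARTER_SECONDS:
        mean = mean_rest if rest else mean_up
        floor = cfg.min_rest_s if rest else cfg.min_upright_s
        d = max(1, int(round(max(rng.exponential(mean), floor))))
        d = min(d, QUARTER_SECONDS - t)
        episodes.append((rest, d))
        t += d
        rest = not rest
    return episodes


def simulate_ethogram(config: ScenarioConfig,
                      parturition_time="2022-05-15 08:00:00",
                      animal_id: str | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Ethogram, BoutTable]:
    """Generate a ground-truth ethogram and its rest-bout table.

    Returns the lying/sitting event ethogram (what a video observer would
    code) together with the ground-truth rest BoutTable (what the leg
    sensor should ideally recover: sitting absorbed into rest).
    Reproducible given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if animal_id is None:
        animal_id = f"sim_{config.housing}"
    part = pd.Timestamp(parturition_time)
    window_start = part.normalize() + pd.Timedelta(days=min(config.days))

    # generate per-quarter, then coalesce same-state neighbours so that
    # rest spanning a quarter boundary is a single ground-truth bout
    episodes: list[list] = []  # [is_rest, start_s, stop_s] from window_start
    day0 = min(config.days)
    for day in sorted(config.days):
        base = (day - day0) * 86400
        for quarter, hour in _QUARTER_HOURS.items():
            p, r = config.target(day, quarter)
            t = base + hour * 3600
            for rest, d in _quarter_episodes(rng, p, r, config):
                if episodes and episodes[-1][0] == rest and episodes[-1][2] == t:
                    episodes[-1][2] = t + d
                else:
                    episodes.append([rest, t, t + d])
                t += d

    truth_records = []
    event_records = []
    for rest, s0, s1 in episodes:
        if not rest:
            continue
        start = window_start + pd.Timedelta(seconds=s0)
        truth_records.append({"behavior": "rest", "start": start,
                              "stop": window_start + pd.Timedelta(seconds=s1)})
        t = s0
        for behavior, d in _decompose_rest(rng, s1 - s0, config):
            event_records.append({
                "behavior": behavior,
                "start": window_start + pd.Timedelta(seconds=t),
                "stop": window_start + pd.Timedelta(seconds=t + d)})
            t += d

    window_end = window_start + pd.Timedelta(days=max(config.days) - day0 + 1)
    eth = Ethogram(animal_id,
                   pd.DataFrame(event_records,
                                columns=["behavior", "start", "stop"]),
                   (window_start, window_end))
    truth = BoutTable.from_records(animal_id, truth_records,
                                   source="ethogram_merged")
    return eth, truth


def _cos_deg(angle_deg: np.ndarray) -> np.ndarray:
    # sin(90 - a) == cos(a) but is exact at the endpoints: angle 0 -> 1.0,
    # angle 90 -> 0.0, which the noise-free tests rely on
    return np.sin(np.deg2rad(90.0 - angle_deg))


def render_accel(eth: Ethogram, model: SensorModel, window=None,
                 rng: np.random.Generator | None = None,
                 seed: int = 0) -> AccelTrace:
    """Render a synthetic y-axis trace for an ethogram.

    One leg angle is drawn per posture episode (a lain-on leg does not
    wander), plus per-sample Gaussian noise and transition bursts. Time not
    covered by an event is upright.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if window is None:
        window = eth.observation_window
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    period_s = 1.0 / model.rate
    n = int(np.floor(((w1 - w0).total_seconds() - 1e-9) / period_s)) + 1
    times = w0.to_datetime64() + (np.arange(n) * 1e9 * period_s).astype("timedelta64[ns]")

    # 0 = upright, 1 = lying, 2 = sitting
    codes = {"lying": 1, "sitting": 2}
    states = np.zeros(n, dtype=np.int8)
    for r in eth.events.itertuples():
        i0 = int(np.ceil((r.start - w0).total_seconds() / period_s - 1e-9))
        i1 = int(np.ceil((r.stop - w0).total_seconds() / period_s - 1e-9))
        states[max(i0, 0):min(i1, n)] = codes[r.behavior]

    means = np.array([model.standing_angle_mean, model.lying_angle_mean,
                      model.sitting_angle_mean])
    sds = np.array([model.standing_angle_sd, model.lying_angle_sd,
                    model.sitting_angle_sd])

    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [n]))
    angles = np.empty(n, dtype=float)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        st = states[b0]
        a = rng.normal(means[st], sds[st]) if sds[st] > 0 else means[st]
        angles[b0:b1] = np.clip(a, 0.0, 90.0)

    y = _cos_deg(angles)
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, n)
    if model.burst_sd > 0 and model.burst_duration_s > 0:
        half = model.burst_duration_s / 2.0 * model.rate
        for b in change:
            i0 = max(int(np.ceil(b - half)), 0)
            i1 = min(int(np.ceil(b + half)), n)
            if i1 > i0:
                y[i0:i1] = y[i0:i1] + rng.normal(0.0, model.burst_sd, i1 - i0)

    return AccelTrace.from_arrays(eth.animal_id, times, y,
                                  nominal_rate=model.rate)


_PRESET_DAYS = tuple(range(-3, 28))
_ANCHOR_DAYS = (-3, -1, 0, 1, 2, 5, 10, 15, 20, 24, 27)

_PRESETS = {
    # crate: bouts rise toward parturition (nest-building without material),
    # peak about five per 6 h at day 0, collapse right after, then recover
    # moderately; lying dips before parturition, peaks after, dips days
    # 5-20, rises toward weaning
    "crate_default": dict(
        housing="crate",
        rate_day=(2.5, 4.5, 5.0, 1.0, 0.5, 1.0, 1.5, 2.0, 2.5, 2.5, 3.0),
        prop_day=(0.70, 0.60, 0.65, 0.92, 0.90, 0.75, 0.65, 0.65, 0.65, 0.72, 0.80),
    ),
    # free: bouts start high, fall to a post-parturition low, stay flat to
    # day 15, climb to about eight per 6 h by day 20 (nest leaving); lying
    # rises toward parturition, stays high, falls toward weaning
    "free_default": dict(
        housing="free",
        rate_day=(6.0, 4.5, 3.0, 1.0, 1.0, 1.2, 1.5, 1.5, 8.0, 7.5, 7.0),
        prop_day=(0.55, 0.70, 0.80, 0.90, 0.90, 0.88, 0.85, 0.85, 0.70, 0.65, 0.60),
    ),
}


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Documented scenario config for one housing system.

    Both presets keep the sows lying nearly all of the time between 18:00
    and 24:00 on every day (early-night proportion 0.97) and differ in the
    daytime/late-night day-courses described in the module docstring.
    """
    if name not in _PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    params = _PRESETS[name]
    return ScenarioConfig(
        housing=params["housing"],
        days=_PRESET_DAYS,
        proportion={"default": (_ANCHOR_DAYS, params["prop_day"]),
                    "early_night": ((0,), (0.97,))},
        rate={"default": (_ANCHOR_DAYS, params["rate_day"]),
              "early_night": ((0,), (1.5,))},
        seed=seed,
    )
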