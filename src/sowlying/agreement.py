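"""Method-agreement analysis: sitting reconciliation and the intraclass
correlation coefficient.

A hind-leg-mounted accelerometer cannot see transitional sitting — the leg
is oriented the same whether the sow sits or lies — so the sensor reports
one *rest* bout where video coding reports lying interrupted by brief
sitting. :func:`merge_transitional_sitting` applies the reconciliation rule
to the video ethogram: sitting bouts between lying bouts, before standing
up, or before lying down are absorbed into the surrounding rest bout;
free-standing sitting (no adjacent lying) stays upright.

Agreement between the two methods is quantified with a two-way
random-effects intraclass correlation on a subjects x methods ratings
matrix (subjects are sow x 24-h periods). The default form is McGraw-Wong
ICC(A,1): single measure, absolute agreement. With row mean square MSR,
column mean square MSC and error mean square MSE from the two-way ANOVA,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the standard F-based 95% confidence interval. The consistency form
ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE) is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BoutTable, Ethogram, intervals_overlap_seconds
from .errors import DegenerateMatrixError, ParameterError, ValidationError

logger = logging.getLogger("sowlying")


def merge_transitional_sitting(eth: Ethogram,
                               adjacency_tolerance: float = 1.0) -> BoutTable:
    """Collapse lying/sitting chains of a video ethogram into rest bouts.

    Every maximal chain of events in which consecutive events are
    contiguous (gap <= ``adjacency_tolerance`` seconds) and which contains
    at least one lying event becomes one rest bout spanning the chain;
    sitting chains with no lying event are discarded (the sow counts as
    upright). The tolerance absorbs sub-second slivers video coding can
    leave between consecutive events; default one sample at 1 Hz.
    """
    records = []
    chain: list = []

    def flush():
        if chain and any(b == "lying" for b, _, _ in chain):
            records.append({"behavior": "rest",
                            "start": chain[0][1], "stop": chain[-1][2]})

    for r in eth.events.itertuples():
        if chain and (r.start - chain[-1][2]).total_seconds() <= adjacency_tolerance:
            chain.append((r.behavior, r.start, r.stop))
        else:
            flush()
            chain = [(r.behavior, r.start, r.stop)]
    flush()
    return BoutTable.from_records(eth.animal_id, records, source="ethogram_merged")


def build_ratings(video: BoutTable, sensor: BoutTable, windows,
                  measure: str = "bout_count", sensor_coverage=None,
                  min_coverage_fraction: float = 0.75) -> pd.DataFrame:
    """Assemble the subjects x methods ratings matrix for the ICC.

    Parameters
    ----------
    windows : iterable of (subject_id, start, stop)
        Non-overlapping rating windows (typically sow x 24-h periods).
    measure : {"bout_count", "lying_seconds"}
        Bout counts use start-attribution; seconds use interval
        intersection with the window.
    sensor_coverage : list of (start, stop), optional
        Valid sensor intervals. Windows whose coverage fraction falls below
        ``min_coverage_fraction`` are dropped with a logged count,
        mirroring the exclusion of faulty recordings; ``None`` assumes full
        coverage.

    Returns
    -------
    DataFrame indexed by subject_id with columns ``video`` and ``sensor``.
    """
    if measure not in ("bout_count", "lying_seconds"):
        raise ParameterError(f"unknown measure {measure!r}")
    rows = {}
    n_dropped = 0
    for subject_id, start, stop in windows:
        start, stop = pd.Timestamp(start), pd.Timestamp(stop)
        if sensor_coverage is not None:
            cov = intervals_overlap_seconds(sensor_coverage, start, stop)
            if cov < min_coverage_fraction * (stop - start).total_seconds():
                n_dropped += 1
                continue
        if measure == "bout_count":
            rows[subject_id] = (video.count_starting_in(start, stop),
                                sensor.count_starting_in(start, stop))
        else:
            rows[subject_id] = (video.seconds_in(start, stop),
                                sensor.seconds_in(start, stop))
    if n_dropped:
        logger.warning("build_ratings: dropped %d windows with sensor "
                       "coverage below %.0f%%", n_dropped,
                       100 * min_coverage_fraction)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["video", "sensor"]).astype(float)


@dataclass
class ICCResult:
    """Intraclass correlation estimate with its confidence interval and the
    two-way ANOVA mean squares it was computed from."""

    estimate: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    form: str = "A,1"
    confidence: float = 0.95

    def summary(self) -> str:
        lines = [
            f"Intraclass correlation ICC({self.form})",
            "=" * 38,
            f"subjects (n)        {self.n:>12d}",
            f"methods  (k)        {self.k:>12d}",
            f"estimate            {self.estimate:>12.4f}",
            f"{int(self.confidence * 100)}% CI              "
            f"[{self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"MS rows             {self.ms_rows:>12.4f}",
            f"MS cols             {self.ms_cols:>12.4f}",
            f"MS error            {self.ms_error:>12.4f}",
        ]
        return "\n".join(lines)


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, ss_total


def icc_agreement(m, confidence: float = 0.95, form: str = "A,1") -> ICCResult:
    """Two-way random-effects ICC of a complete subjects x methods matrix.

    Rows with any missing cell are dropped (with a logged count) before
    the ANOVA. A matrix with zero total variance has no defined ICC and
    raises :class:`DegenerateMatrixError` rather than returning a number.
    """
    if form not in ("A,1", "C,1"):
        raise ParameterError(f"unknown ICC form {form!r}")
    if not 0 < confidence < 1:
        raise ParameterError(f"confidence must be in (0, 1), got {confidence}")
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects x methods matrix")
    complete = np.isfinite(x).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("icc_agreement: dropped %d subjects with missing cells",
                       n_dropped)
        x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need at least 2 subjects and 2 methods, "
                              f"got {n} x {k}")

    msr, msc, mse, ss_total = _anova_mean_squares(x)
    scale = max(1.0, float(np.abs(x).max()) ** 2)
    if ss_total <= 1e-12 * scale:
        raise DegenerateMatrixError(
            "ratings matrix has zero total variance; ICC undefined")

    alpha = 1.0 - confidence
    if form == "A,1":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df of the MSC/MSE contrast (McGraw & Wong)
        if mse > 0:
            fj = msc / mse
            a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
            vn = (k - 1) * (n - 1) * a ** 2
            vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + \
                (n * (1 + (k - 1) * icc) - k * icc) ** 2
            v = vn / vd
        else:
            v = float((k - 1) * (n - 1))
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - fl * mse) / (
            fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (fu * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu * msr)
    else:  # C,1
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse > 0:
            fobs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
            lower = (fl - 1) / (fl + k - 1)
            upper = (fu - 1) / (fu + k - 1)
        else:
            lower = upper = icc
    lower = float(np.clip(min(lower, icc), -1.0, 1.0))
    upper = float(np.clip(max(upper, icc), -1.0, 1.0))
    return ICCResult(estimate=float(icc), ci_low=lower, ci_high=upper,
                     ms_rows=msr, ms_cols=msc, ms_error=mse, n=n, k=k,
                     form=form, confidence=confidence)
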