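"""Wearable-stream circadian analysis chain.

Pipeline: raw per-subject streams (activity counts at sub-minute cadence,
or heart-rate / RR-interval series) are aggregated to one value per
calendar minute (summed for activity counts, averaged for rates), times
are recast as hours since midnight of each subject's first day, a 24-h
fixed-period cosinor is fit per subject, and the subject-level MESOR /
amplitude / acrophase estimates are compared between age groups — MESOR
and amplitude with the exact two-sided Wilcoxon rank-sum test, acrophase
with the two-sample Kuiper test, which respects the circular scale.

Minutes with no data are simply absent from the fit; no imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import fit_cosinor
from .nonparam import kuiper_two_sample, wilcoxon_exact

__all__ = [
    "ActivitySeries",
    "GroupComparison",
    "SubjectCosinorSummary",
    "aggregate_minutes",
    "analyze_wearables",
    "compare_groups",
    "hours_since_start",
    "read_wearables_csv",
    "subject_cosinor",
]


@dataclass
class ActivitySeries:
    """One subject's timestamped stream (activity counts, bpm, or RR ms)."""

    subject_id: str
    group: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not self.timestamps.is_monotonic_increasing:
            warnings.warn(
                f"timestamps for {self.subject_id} were unsorted; sorting",
                stacklevel=2,
            )
            order = np.argsort(self.timestamps)
            self.timestamps = self.timestamps[order]
            self.values = self.values[order]


@dataclass(frozen=True)
class SubjectCosinorSummary:
    subject_id: str
    group: str
    mesor: float
    amplitude: float
    acrophase: float


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    test: str
    statistic: float
    p: float
    median_young: float
    median_old: float


def aggregate_minutes(series: ActivitySeries, how: str = "sum") -> ActivitySeries:
    """Collapse a sub-minute stream to one value per calendar minute.

    Activity counts are summed within each minute; heart-rate or
    RR-interval streams should pass ``how="mean"`` (summing rates is
    meaningless).  Minutes with no samples are absent from the output, not
    zero-filled.
    """
    if how not in ("sum", "mean"):
        raise ValueError(f"how must be 'sum' or 'mean', got {how!r}")
    minutes = series.timestamps.floor("min")
    agg = pd.Series(series.values, index=minutes).groupby(level=0).agg(how)
    return ActivitySeries(
        subject_id=series.subject_id,
        group=series.group,
        timestamps=pd.DatetimeIndex(agg.index),
        values=agg.to_numpy(),
    )


def hours_since_start(timestamps: pd.DatetimeIndex, origin=None) -> np.ndarray:
    """Hours elapsed since midnight of the first measurement day.

    ``origin`` overrides the default origin (midnight preceding the first
    timestamp).  Fractional hours are preserved.
    """
    ts = pd.DatetimeIndex(timestamps)
    if len(ts) == 0:
        raise ValueError("timestamps must be non-empty")
    if origin is None:
        origin = ts[0].normalize()
    return ((ts - pd.Timestamp(origin)) / pd.Timedelta(hours=1)).to_numpy(dtype=float)


def subject_cosinor(series: ActivitySeries, period: float = 24.0) -> SubjectCosinorSummary:
    """Fixed-period cosinor fit of one subject's stream."""
    t = hours_since_start(series.timestamps)
    fit = fit_cosinor(series.values, t, period)
    return SubjectCosinorSummary(
        subject_id=series.subject_id,
        group=series.group,
        mesor=fit.mesor,
        amplitude=fit.amplitude,
        acrophase=fit.acrophase,
    )


def compare_groups(
    summaries,
    parameter: str,
    *,
    nboots: int = 10000,
    seed: int = 0,
) -> GroupComparison:
    """Compare one cosinor parameter between the young and old groups.

    ``parameter`` is one of ``mesor``, ``amplitude`` (Wilcoxon rank-sum
    exact) or ``acrophase`` (two-sample Kuiper with ``nboots`` resamples).
    Invariant to the order of ``summaries``.
    """
    if parameter not in ("mesor", "amplitude", "acrophase"):
        raise ValueError(f"unknown parameter {parameter!r}")
    table = _summaries_frame(summaries)
    young = table.loc[table["group"] == "young", parameter].to_numpy()
    old = table.loc[table["group"] == "old", parameter].to_numpy()
    if young.size < 2 or old.size < 2:
        raise ValueError("need at least 2 subjects per group")
    if parameter == "acrophase":
        res = kuiper_two_sample(young, old, nboots=nboots, seed=seed)
        stat, p, test = res.v, res.p, "kuiper"
    else:
        res = wilcoxon_exact(young, old)
        stat, p, test = res.w, res.p_two_sided, "wilcoxon_exact"
    return GroupComparison(
        parameter=parameter,
        test=test,
        statistic=stat,
        p=p,
        median_young=float(np.median(young)),
        median_old=float(np.median(old)),
    )


def _summaries_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "mesor": s.mesor,
                "amplitude": s.amplitude,
                "acrophase": s.acrophase,
            }
            for s in summaries
        ]
    )


def read_wearables_csv(path) -> list[ActivitySeries]:
    """Read a long-format CSV (subject_id, group, timestamp, value)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"subject_id", "group", "timestamp", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wearables CSV missing columns: {sorted(missing)}")
    series = []
    for (subject, group), sub in df.groupby(["subject_id", "group"], sort=True):
        series.append(
            ActivitySeries(
                subject_id=str(subject),
                group=str(group),
                timestamps=pd.DatetimeIndex(sub["timestamp"]),
                values=sub["value"].to_numpy(dtype=float),
            )
        )
    return series


def analyze_wearables(
    series_list,
    kind: str = "activity",
    *,
    period: float = 24.0,
    nboots: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: minute aggregation, per-subject cosinor, group tests.

    ``kind="activity"`` sums counts within minutes; any other kind (heart
    rate, RR intervals) averages them.  Returns (per-subject summary table,
    group-comparison table).
    """
    how = "sum" if kind == "activity" else "mean"
    summaries = []
    for s in series_list:
        minute = aggregate_minutes(s, how=how)
        summaries.append(subject_cosinor(minute, period=period))
    summary_df = _summaries_frame(summaries)
    comparisons = [
        compare_groups(summary_df, p, nboots=nboots, seed=seed)
        for p in ("mesor", "amplitude", "acrophase")
    ]
    comp_df = pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "test": c.test,
                "statistic": c.statistic,
                "p": c.p,
                "median_young": c.median_young,
                "median_old": c.median_old,
            }
            for c in comparisons
        ]
    )
    return summary_df, comp_df
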