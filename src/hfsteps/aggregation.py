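"""Two-stage summary-statistic battery over minute-level step streams.

Stage one summarises each patient-day of 1440 per-minute step counts (total,
mean, SD, five-number summary, IQR, skewness, kurtosis, zero fraction).
Stage two aggregates each daily statistic across the monitoring period with
max / min / mean / SD, and additionally summarises the whole period as one
concatenated minute stream (the "pooled" or 2-week statistics).

Conventions, applied uniformly:

* quantiles: linear interpolation between order statistics;
* SD: sample standard deviation (n-1 denominator) at both stages;
* skewness: m3 / m2^(3/2) and kurtosis: m4 / m2^2 (Pearson, non-excess),
  from n-denominator central moments without small-sample bias correction;
* a statistic that cannot be computed (constant day, fewer than two
  contributing days for an SD) is NaN, the battery's "not computable" marker.

Zeros - whether from inactivity or from the tracker being off-body - enter
every statistic; the nonzero-only view exists solely in
:func:`nonzero_distribution`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nyha import NYHAGroup, regroup_label
from .step_io import Cohort, MinuteStepSeries, PatientRecord, MINUTES_PER_DAY

#: Daily statistics aggregated across days, in battery order.
DAILY_STATS = (
    "total", "mean", "sd", "min", "q1", "median", "q3", "max", "iqr",
    "skewness", "kurtosis",
)

#: Cross-day aggregates applied to each daily statistic.
CROSS_DAY_AGGREGATES = ("max", "min", "mean", "sd")

#: Whole-period statistics over the concatenated minutes.
PERIOD_STATS = DAILY_STATS + ("zero_fraction",)

#: Systematic names of every feature a patient contributes to the battery.
FEATURE_NAMES = tuple(
    f"{agg}_of_daily_{stat}"
    for stat in DAILY_STATS
    for agg in CROSS_DAY_AGGREGATES
) + tuple(f"period_{stat}" for stat in PERIOD_STATS)


@dataclass
class DailySummary:
    """First-aggregation statistics for one patient-day."""

    total: float
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    iqr: float
    skewness: float
    kurtosis: float
    n_minutes: int
    zero_fraction: float


def _battery(x: np.ndarray) -> dict[str, float]:
    """The shared statistic battery over one vector of minute counts."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered**2))
    if m2 > 0.0:
        skewness = float(np.mean(centered**3)) / m2**1.5
        kurtosis = float(np.mean(centered**4)) / m2**2
    else:
        skewness = np.nan
        kurtosis = np.nan
    q0, q1, q2, q3, q4 = np.percentile(x, [0, 25, 50, 75, 100])
    return {
        "total": float(x.sum()),
        "mean": mean,
        "sd": float(x.std(ddof=1)) if n > 1 else np.nan,
        "min": float(q0),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(q4),
        "iqr": float(q3 - q1),
        "skewness": skewness,
        "kurtosis": kurtosis,
        "zero_fraction": float(np.mean(x == 0)),
    }


def daily_summary(series: MinuteStepSeries | np.ndarray) -> DailySummary:
    """Summarise one dense patient-day of 1440 per-minute counts.

    A constant day (most commonly all zeros from a non-wear day) has zero
    variance, so skewness and kurtosis are NaN while the order statistics are
    still returned.
    """
    counts = series.counts if isinstance(series, MinuteStepSeries) else np.asarray(series)
    if counts.shape != (MINUTES_PER_DAY,):
        raise ValueError(
            f"daily_summary expects {MINUTES_PER_DAY} minutes, "
            f"got {counts.shape}"
        )
    stats = _battery(counts)
    return DailySummary(n_minutes=MINUTES_PER_DAY, **stats)


def aggregate_days(
    summaries: Sequence[DailySummary],
    pooled_minutes: np.ndarray,
) -> dict[str, float]:
    """Second aggregation: the 4 x 11 cross-day grid plus pooled-period stats.

    Days where a statistic is NaN (constant days) are skipped for that
    statistic's aggregates rather than propagating missingness; an SD over
    fewer than two contributing days is NaN.  Returns a flat mapping keyed by
    the systematic names in :data:`FEATURE_NAMES`.
    """
    if not summaries:
        raise ValueError("aggregate_days requires at least one day")
    features: dict[str, float] = {}
    for stat in DAILY_STATS:
        values = np.array([getattr(s, stat) for s in summaries], dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            agg = {"max": np.nan, "min": np.nan, "mean": np.nan, "sd": np.nan}
        else:
            agg = {
                "max": float(values.max()),
                "min": float(values.min()),
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
            }
        for name in CROSS_DAY_AGGREGATES:
            features[f"{name}_of_daily_{stat}"] = agg[name]

    pooled = np.asarray(pooled_minutes)
    if pooled.size != MINUTES_PER_DAY * len(summaries):
        raise ValueError(
            "pooled_minutes length does not match the summarised days"
        )
    for stat, value in _battery(pooled).items():
        features[f"period_{stat}"] = value
    return features


def patient_features(patient: PatientRecord) -> dict[str, float]:
    """Full feature battery (cross-day grid + pooled period) for one patient."""
    summaries = [daily_summary(d) for d in patient.days]
    return aggregate_days(summaries, patient.pooled_counts())


def feature_matrix(cohort: Cohort) -> pd.DataFrame:
    """One row per patient: every battery feature plus label and group.

    This is the analysis table the rank-test battery consumes; feature
    columns follow :data:`FEATURE_NAMES`.
    """
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "nyha_label": p.nyha_label,
            "group": regroup_label(p.nyha_label).value,
        }
        row.update(patient_features(p))
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("patient_id")
    return frame[["nyha_label", "group", *FEATURE_NAMES]]


def zero_profile(patient: PatientRecord) -> float:
    """Fraction of all recorded minutes that are exactly zero.

    With this tracker a zero conflates inactivity and non-wear, so this is a
    joint (in)activity/adherence measure, not wear time.
    """
    if not patient.days:
        raise ValueError("zero_profile requires at least one day")
    pooled = patient.pooled_counts()
    return float(np.mean(pooled == 0))


def nonzero_distribution(cohort: Cohort, group: NYHAGroup) -> pd.DataFrame:
    """Histogram of nonzero per-minute step values for one analysis group.

    Tidy output with one row per (patient, step value): columns
    ``patient_id``, ``steps_per_minute``, ``n_minutes``.  The pooled group
    histogram is the sum over patients; a group with no nonzero minutes
    yields an empty frame.
    """
    rows = []
    for p in cohort:
        if regroup_label(p.nyha_label) is not group:
            continue
        pooled = p.pooled_counts()
        values, counts = np.unique(pooled[pooled > 0], return_counts=True)
        for v, c in zip(values, counts):
            rows.append(
                {"patient_id": p.patient_id, "steps_per_minute": int(v),
                 "n_minutes": int(c)}
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "steps_per_minute", "n_minutes"]
    )
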