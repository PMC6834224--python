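"""End-to-end report assembly: demographics, the tested battery partitioned
by significance, the all-zero exclusion rule, adherence and nonzero-cadence
tables, and the lifestyle categorisation helper.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import feature_matrix, nonzero_distribution, zero_profile
from .nyha import NYHAGroup, demographics_table, group_assignments, group_counts
from .stats import TestResult, battery_frame, run_battery
from .step_io import Cohort

#: Demographic variables entered into the rank-test battery alongside the
#: step features; binary variables are coded 0/1 as in the published tables
#: (sex: male=0 female=1; righthanded and wristband-right: no=0 yes=1).
DEMOGRAPHIC_FEATURES = (
    "sex", "age", "height_cm", "weight_kg", "bmi", "righthanded", "wrist_right",
)


@dataclass
class BatteryReport:
    """The battery partitioned the way the result tables are laid out:
    significant (p <= .05), nonsignificant (including not-computable rows
    kept with an N/A p), and features excluded because every patient's value
    was exactly zero."""

    significant: list[TestResult]
    nonsignificant: list[TestResult]
    excluded: list[str]
    alpha_flags: tuple[float, float] = (0.05, 0.01)

    @property
    def all_feature_names(self) -> list[str]:
        return (
            [r.feature_name for r in self.significant]
            + [r.feature_name for r in self.nonsignificant]
            + list(self.excluded)
        )


def analysis_matrix(cohort: Cohort) -> pd.DataFrame:
    """Feature battery plus 0/1-coded demographics, one row per patient."""
    features = feature_matrix(cohort)
    meta = cohort.metadata_frame().set_index("patient_id")
    demo = pd.DataFrame(
        {
            "sex": (meta["sex"] == "female").astype(float),
            "age": meta["age"].astype(float),
            "height_cm": meta["height_cm"].astype(float),
            "weight_kg": meta["weight_kg"].astype(float),
            "bmi": meta["bmi"].astype(float),
            "righthanded": meta["righthanded"].astype(float),
            "wrist_right": meta["wrist_right"].astype(float),
        }
    )
    return features.join(demo)


def build_report(cohort: Cohort) -> BatteryReport:
    """Run aggregation -> rank-test battery -> significance partition.

    A feature is excluded only when it is exactly zero for every patient
    (hence zero group medians everywhere) - the zero-inflation casualty rule
    that removes the quantile-based statistics.  Features that are constant
    but nonzero stay in the nonsignificant table with an N/A p-value.
    """
    matrix = analysis_matrix(cohort)
    grouping = group_assignments(cohort)
    value_cols = [c for c in matrix.columns if c not in ("nyha_label", "group")]
    values = matrix[value_cols]

    excluded = [c for c in value_cols if (values[c].fillna(0) == 0).all()]
    tested = values.drop(columns=excluded)
    results = run_battery(tested, grouping)
    significant = [r for r in results if r.flag_05]
    nonsignificant = [r for r in results if not r.flag_05]
    return BatteryReport(
        significant=significant,
        nonsignificant=nonsignificant,
        excluded=excluded,
    )


def lifestyle_class(mean_daily_total: float) -> str:
    """Categorise a mean daily step total against lifestyle thresholds:
    <5000 steps/day sedentary, 5000-7499 low active, 7500+ above that."""
    if mean_daily_total < 0:
        raise ValueError("mean daily total must be >= 0")
    if mean_daily_total < 5000:
        return "sedentary"
    if mean_daily_total < 7500:
        return "low_active"
    return "above_low_active"


def adherence_report(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-patient zero-minute fractions plus cohort mean/SD/min/max.

    The cohort mean tracks how much of the data stream is ambiguous zeros
    (inactivity or non-wear); SD uses the n-1 denominator.
    """
    rows = [
        {"patient_id": p.patient_id, "zero_fraction": zero_profile(p)}
        for p in cohort
    ]
    table = pd.DataFrame(rows)
    zf = table["zero_fraction"].to_numpy()
    summary = {
        "mean": float(zf.mean()),
        "sd": float(zf.std(ddof=1)) if zf.size > 1 else 0.0,
        "min": float(zf.min()),
        "max": float(zf.max()),
    }
    return table, summary


def write_report_dir(cohort: Cohort, out_dir: str | os.PathLike) -> None:
    """Write the full tabular report bundle for one cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    demographics = pd.concat(
        [demographics_table(cohort, by="group"),
         demographics_table(cohort, by="raw_class")],
        ignore_index=True,
    )
    demographics.to_csv(out / "demographics.csv", index=False)
    group_counts(cohort).to_csv(out / "group_counts.csv", index=False)

    report = build_report(cohort)
    battery_frame(report.significant).to_csv(
        out / "battery_significant.csv", index=False
    )
    battery_frame(report.nonsignificant).to_csv(
        out / "battery_nonsignificant.csv", index=False
    )
    (out / "excluded.txt").write_text(
        "".join(f"{name}\n" for name in report.excluded)
    )

    table, summary = adherence_report(cohort)
    table.to_csv(out / "adherence.csv", index=False)
    pd.DataFrame([summary]).to_csv(out / "adherence_summary.csv", index=False)

    hist = pd.concat(
        [
            nonzero_distribution(cohort, g).assign(group=g.value)
            for g in NYHAGroup
        ],
        ignore_index=True,
    )
    hist.to_csv(out / "nonzero_hist.csv", index=False)
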