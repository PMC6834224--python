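"""NYHA borderline-class regrouping and grouped demographics.

Heart-failure clinics often record borderline functional classes (I/II,
II/III) when a patient's symptoms straddle two NYHA levels.  For a two-group
analysis these are merged with the more extreme class in the mix: I/II joins
II (group II*), II/III joins III (group III*), because a borderline patient
necessarily exhibits more limitation than the milder class alone implies.
"""

from __future__ import annotations

import enum
import math

import numpy as np
import pandas as pd

from .step_io import Cohort, ValidationError

#: Continuous demographics summarised as Q1 | median | Q3.
CONTINUOUS_VARS = ("age", "height_cm", "weight_kg", "bmi")


class NYHAGroup(enum.Enum):
    """The two analysis groups formed by merging borderline labels."""

    II_STAR = "II*"
    III_STAR = "III*"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_REGROUP = {
    "I/II": NYHAGroup.II_STAR,
    "II": NYHAGroup.II_STAR,
    "II/III": NYHAGroup.III_STAR,
    "III": NYHAGroup.III_STAR,
}


def regroup_label(label: str) -> NYHAGroup:
    """Map a raw NYHA label onto its analysis group.

    Borderline labels go to the most extreme class in the mix: I/II -> II*,
    II/III -> III*.  Classes I and IV are outside the study population and
    are rejected.
    """
    try:
        return _REGROUP[label]
    except KeyError:
        raise ValidationError(
            f"cannot regroup nyha_label {label!r}; expected one of "
            f"{sorted(_REGROUP)}"
        ) from None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def group_counts(cohort: Cohort) -> pd.DataFrame:
    """Participant and male counts per analysis group, with percentages.

    ``percent`` is the group's share of the cohort; ``percent_male`` is the
    male share within the group.  Percentages are rounded half-up to integers,
    matching the usual table formatting.
    """
    rows = []
    n_total = len(cohort)
    for group in NYHAGroup:
        members = [p for p in cohort if regroup_label(p.nyha_label) is group]
        n = len(members)
        n_male = sum(p.sex == "male" for p in members)
        rows.append(
            {
                "group": group.value,
                "n": n,
                "percent": _round_half_up(100.0 * n / n_total),
                "n_male": n_male,
                "percent_male": (
                    _round_half_up(100.0 * n_male / n) if n else 0
                ),
            }
        )
    return pd.DataFrame(rows)


def demographics_table(cohort: Cohort, by: str = "group") -> pd.DataFrame:
    """Quartile summaries of the continuous demographics per stratum.

    ``by='raw_class'`` stratifies on the original four labels, ``by='group'``
    on the regrouped II*/III* levels.  Quartiles use linear interpolation
    between order statistics, the same convention applied throughout the
    pipeline.  Output is tidy: one row per (stratum, variable, statistic).
    """
    if by == "raw_class":
        strata = [
            (label, [p for p in cohort if p.nyha_label == label])
            for label in ("I/II", "II", "II/III", "III")
        ]
    elif by == "group":
        strata = [
            (g.value, [p for p in cohort if regroup_label(p.nyha_label) is g])
            for g in NYHAGroup
        ]
    else:
        raise ValueError(f"by must be 'raw_class' or 'group', got {by!r}")

    rows = []
    for name, members in strata:
        rows.append(
            {"stratum": name, "variable": "n", "statistic": "count",
             "value": float(len(members))}
        )
        rows.append(
            {"stratum": name, "variable": "n_male", "statistic": "count",
             "value": float(sum(p.sex == "male" for p in members))}
        )
        for var in CONTINUOUS_VARS:
            values = np.array([getattr(p, var) for p in members], dtype=float)
            for stat, q in (("q1", 25), ("median", 50), ("q3", 75)):
                value = float(np.percentile(values, q)) if len(values) else np.nan
                rows.append(
                    {"stratum": name, "variable": var, "statistic": stat,
                     "value": value}
                )
    return pd.DataFrame(rows)


def group_assignments(cohort: Cohort) -> pd.Series:
    """Per-patient NYHAGroup, indexed by patient_id."""
    return pd.Series(
        {p.patient_id: regroup_label(p.nyha_label) for p in cohort},
        name="group",
    )
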