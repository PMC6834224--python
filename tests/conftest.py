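"""Shared fixtures and the independent brute-force statistic oracle.

The oracle deliberately avoids the implementation's numpy code paths:
quantiles are computed by hand on a sorted list, moments with math.fsum.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pytest
from hypothesis import settings

from hfsteps import (
    Cohort,
    GeneratorConfig,
    MinuteStepSeries,
    PatientRecord,
    MINUTES_PER_DAY,
    generate_cohort,
)

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


# -- independent brute-force oracle ----------------------------------------

def oracle_quantile(sorted_xs: Sequence[float], q: float) -> float:
    """Linear interpolation between order statistics at position (n-1)q."""
    n = len(sorted_xs)
    pos = (n - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    return sorted_xs[lo] + (pos - lo) * (sorted_xs[hi] - sorted_xs[lo])


def oracle_summary(counts: Sequence[float]) -> dict[str, float]:
    """Brute-force reimplementation of the daily statistic battery."""
    xs = sorted(float(v) for v in counts)
    n = len(xs)
    mean = math.fsum(xs) / n
    m2 = math.fsum((x - mean) ** 2 for x in xs) / n
    if m2 > 0:
        skewness = (math.fsum((x - mean) ** 3 for x in xs) / n) / m2**1.5
        kurtosis = (math.fsum((x - mean) ** 4 for x in xs) / n) / m2**2
    else:
        skewness = math.nan
        kurtosis = math.nan
    q1 = oracle_quantile(xs, 0.25)
    q3 = oracle_quantile(xs, 0.75)
    return {
        "total": math.fsum(xs),
        "mean": mean,
        "sd": math.sqrt(math.fsum((x - mean) ** 2 for x in xs) / (n - 1)),
        "min": xs[0],
        "q1": q1,
        "median": oracle_quantile(xs, 0.5),
        "q3": q3,
        "max": xs[-1],
        "iqr": q3 - q1,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "zero_fraction": sum(x == 0 for x in xs) / n,
    }


def oracle_cross_day(values: Sequence[float]) -> dict[str, float]:
    """Brute-force max/min/mean/SD over the computable daily values."""
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return {k: math.nan for k in ("max", "min", "mean", "sd")}
    mean = math.fsum(vals) / len(vals)
    sd = (
        math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        if len(vals) > 1
        else math.nan
    )
    return {"max": max(vals), "min": min(vals), "mean": mean, "sd": sd}


def random_patient_day(rng: np.random.Generator) -> np.ndarray:
    """A random day mixing the regimes the pipeline must survive:
    zero-inflated spiky days, dense noise, and occasional constant days."""
    kind = rng.integers(4)
    if kind == 0:
        return np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    n_active = int(rng.integers(1, 400))
    idx = rng.choice(MINUTES_PER_DAY, n_active, replace=False)
    counts[idx] = rng.integers(1, 131, n_active)
    if kind == 3:
        counts += rng.integers(0, 3, MINUTES_PER_DAY)
    return counts


# -- fixtures ---------------------------------------------------------------

def make_patient(
    pid: str,
    label: str = "II",
    sex: str = "male",
    age: float = 55.0,
    days: list[np.ndarray] | None = None,
    **overrides,
) -> PatientRecord:
    if days is None:
        days = [np.zeros(MINUTES_PER_DAY, dtype=np.int64)]
    fields = dict(
        patient_id=pid,
        nyha_label=label,
        sex=sex,
        age=age,
        height_cm=175.0,
        weight_kg=85.0,
        bmi=27.8,
        righthanded=True,
        wrist_right=False,
    )
    fields.update(overrides)
    return PatientRecord(
        days=[
            MinuteStepSeries(pid, i + 1, counts) for i, counts in enumerate(days)
        ],
        **fields,
    )


@pytest.fixture(scope="session")
def synthetic_cohort() -> Cohort:
    """The default 35/15-patient, 14-day study-sized synthetic cohort."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture()
def table_counts_cohort() -> Cohort:
    """A cohort replaying the published per-class participant and male
    counts: 9 I/II (6 male), 26 II (23 male), 4 II/III (4 male),
    11 III (10 male)."""
    patients = []
    i = 0
    for label, n, n_male in [
        ("I/II", 9, 6), ("II", 26, 23), ("II/III", 4, 4), ("III", 11, 10),
    ]:
        for j in range(n):
            i += 1
            patients.append(
                make_patient(
                    f"P{i:03d}", label=label,
                    sex="male" if j < n_male else "female",
                )
            )
    return Cohort(patients)
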