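"""Data model and CSV readers/writers for minute-resolution step streams.

A patient's monitoring period is a sequence of calendar days, each a dense
vector of 1440 per-minute step counts (PMSC).  Consumer wrist trackers record
a zero both when the wearer is inactive and when the device is off-body, so
zeros are first-class data here: the dense representation never drops them.

On disk the stream uses a sparse long-format CSV dialect (zero minutes may be
omitted); reading restores dense semantics by filling absent minutes with 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

#: Hard sanity ceiling on a per-minute step count.  No human sustains more
#: than ~300 steps/min for a full minute; observed free-living maxima in
#: heart-failure cohorts are nearer 120-130.
STEP_CEILING = 300

#: Raw NYHA labels admitted by the study population (classes I and IV are
#: outside scope; borderline labels I/II and II/III are regrouped downstream).
NYHA_LABELS = ("I/II", "II", "II/III", "III")

STREAM_COLUMNS = ["patient_id", "day_index", "minute", "steps"]
META_COLUMNS = [
    "patient_id",
    "nyha_label",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "bmi",
    "righthanded",
    "wrist_right",
]


class ValidationError(ValueError):
    """Malformed or out-of-contract input data."""


@dataclass
class MinuteStepSeries:
    """One patient-day: a dense vector of 1440 non-negative step counts."""

    patient_id: str
    day_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (MINUTES_PER_DAY,):
            raise ValidationError(
                f"patient {self.patient_id} day {self.day_index}: counts must "
                f"have length {MINUTES_PER_DAY}, got {self.counts.shape}"
            )
        if self.day_index < 1:
            raise ValidationError(
                f"patient {self.patient_id}: day_index must be >= 1, "
                f"got {self.day_index}"
            )
        bad = np.flatnonzero((self.counts < 0) | (self.counts > STEP_CEILING))
        if bad.size:
            m = int(bad[0])
            raise ValidationError(
                f"patient {self.patient_id} day {self.day_index} minute {m}: "
                f"step count {int(self.counts[m])} outside [0, {STEP_CEILING}]"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PatientRecord:
    """Metadata plus the ordered sequence of monitored days for one patient.

    ``bmi`` is cross-checked against weight/(height/100)^2 within 5% when all
    three are present; the monitoring period is nominally 14 days but any
    length >= 1 is accepted.
    """

    patient_id: str
    nyha_label: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    bmi: float
    righthanded: bool
    wrist_right: bool
    days: list[MinuteStepSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nyha_label not in NYHA_LABELS:
            raise ValidationError(
                f"patient {self.patient_id}: unknown nyha_label "
                f"{self.nyha_label!r} (expected one of {NYHA_LABELS})"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id}: sex must be 'male' or 'female', "
                f"got {self.sex!r}"
            )
        indices = [d.day_index for d in self.days]
        if indices != list(range(1, len(indices) + 1)):
            raise ValidationError(
                f"patient {self.patient_id}: day_index values must be "
                f"consecutive starting at 1, got {indices}"
            )
        if all(np.isfinite([self.height_cm, self.weight_kg, self.bmi])):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if self.bmi > 0 and abs(implied - self.bmi) / self.bmi > 0.05:
                raise ValidationError(
                    f"patient {self.patient_id}: bmi {self.bmi:.2f} "
                    f"inconsistent with weight/height ({implied:.2f})"
                )

    @property
    def n_days(self) -> int:
        return len(self.days)

    def pooled_counts(self) -> np.ndarray:
        """Concatenated minutes of every monitored day, in day order."""
        return np.concatenate([d.counts for d in self.days])


@dataclass
class Cohort:
    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValidationError("cohort must contain at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "nyha_label": p.nyha_label,
                "sex": p.sex,
                "age": p.age,
                "height_cm": p.height_cm,
                "weight_kg": p.weight_kg,
                "bmi": p.bmi,
                "righthanded": p.righthanded,
                "wrist_right": p.wrist_right,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows, columns=META_COLUMNS)


def read_cohort(
    stream_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    min_days: int = 1,
) -> Cohort:
    """Read a cohort from a sparse stream CSV plus a metadata CSV.

    Every (patient, day) pair present in the stream becomes a dense
    1440-minute day; minutes absent from the file are filled with 0.
    Patients with fewer than ``min_days`` recorded days are dropped.
    """
    stream = pd.read_csv(stream_path, dtype={"patient_id": str})
    missing = [c for c in STREAM_COLUMNS if c not in stream.columns]
    if missing:
        raise ValidationError(f"stream file missing columns {missing}")
    if stream.empty:
        raise ValidationError("no stream rows")

    meta = pd.read_csv(meta_path, dtype={"patient_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata file missing columns {missing}")
    meta = meta.set_index("patient_id", verify_integrity=True)

    dup = stream.duplicated(subset=["patient_id", "day_index", "minute"])
    if dup.any():
        r = stream[dup].iloc[0]
        raise ValidationError(
            f"duplicate stream row for patient {r['patient_id']} "
            f"day {int(r['day_index'])} minute {int(r['minute'])}"
        )
    bad_minute = (stream["minute"] < 0) | (stream["minute"] >= MINUTES_PER_DAY)
    if bad_minute.any():
        r = stream[bad_minute].iloc[0]
        raise ValidationError(
            f"patient {r['patient_id']} day {int(r['day_index'])}: minute "
            f"{int(r['minute'])} outside [0, {MINUTES_PER_DAY - 1}]"
        )
    bad_steps = (stream["steps"] < 0) | (stream["steps"] > STEP_CEILING)
    if bad_steps.any():
        r = stream[bad_steps].iloc[0]
        raise ValidationError(
            f"patient {r['patient_id']} day {int(r['day_index'])} minute "
            f"{int(r['minute'])}: step count {int(r['steps'])} outside "
            f"[0, {STEP_CEILING}]"
        )

    unknown = sorted(set(stream["patient_id"]) - set(meta.index))
    if unknown:
        raise ValidationError(
            f"stream patients missing from metadata: {unknown}"
        )

    patients: list[PatientRecord] = []
    for pid, prows in stream.groupby("patient_id", sort=True):
        days = []
        for day_index, drows in prows.groupby("day_index", sort=True):
            counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
            counts[drows["minute"].to_numpy()] = drows["steps"].to_numpy()
            days.append(MinuteStepSeries(str(pid), int(day_index), counts))
        if len(days) < min_days:
            continue
        m = meta.loc[pid]
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                nyha_label=str(m["nyha_label"]),
                sex=str(m["sex"]),
                age=float(m["age"]),
                height_cm=float(m["height_cm"]),
                weight_kg=float(m["weight_kg"]),
                bmi=float(m["bmi"]),
                righthanded=bool(m["righthanded"]),
                wrist_right=bool(m["wrist_right"]),
                days=days,
            )
        )
    return Cohort(patients)


def write_cohort(
    cohort: Cohort,
    stream_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> None:
    """Write a cohort in the sparse dialect read back by :func:`read_cohort`.

    Zero minutes are omitted except that an all-zero day emits one sentinel
    row (minute 0, steps 0) so the day survives the round trip.
    """
    frames = []
    for p in cohort:
        for d in p.days:
            nz = np.flatnonzero(d.counts)
            if nz.size == 0:
                nz = np.array([0])
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": p.patient_id,
                        "day_index": d.day_index,
                        "minute": nz,
                        "steps": d.counts[nz],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(stream_path, index=False)
    cohort.metadata_frame().to_csv(meta_path, index=False)
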