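"""Cohort CSV dialect: one patient per row plus a long-format antibiotic file.

Patients are written one per row with missing values as empty fields; the
antibiotic prescriptions go to a companion long-format CSV keyed by
``patient_id`` (one row per course).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .synthetic_cohort import RawAbxRecord, RawPatientRecord

__all__ = ["cohort_to_frames", "frames_to_cohort", "write_cohort", "read_cohort"]

_PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "age",
    "sex",
    "psm_weight",
    "admission_day",
    "covid_test_day",
    "discharge_day",
    "icu_in_day",
    "icu_out_day",
    "survival_days",
    "pct_test_count",
    "ethnicity",
    "imd_decile",
    "n_comorbidities",
]

_DAY_COLUMNS = ["admission_day", "covid_test_day", "discharge_day", "icu_in_day", "icu_out_day"]


def cohort_to_frames(cohort: Iterable[RawPatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into a patient frame and a long-format antibiotic frame."""
    patients = []
    abx = []
    for rec in cohort:
        patients.append({c: getattr(rec, c) for c in _PATIENT_COLUMNS})
        for course in rec.antibiotic_records:
            abx.append(
                {
                    "patient_id": rec.patient_id,
                    "name_text": course.name_text,
                    "dose_text": course.dose_text,
                    "frequency_per_day": course.frequency_per_day,
                    "days": course.days,
                }
            )
    pf = pd.DataFrame(patients, columns=_PATIENT_COLUMNS)
    for col in _DAY_COLUMNS:
        pf[col] = pf[col].astype("Int64")
    af = pd.DataFrame(
        abx, columns=["patient_id", "name_text", "dose_text", "frequency_per_day", "days"]
    )
    return pf, af


def frames_to_cohort(patients: pd.DataFrame, abx: pd.DataFrame) -> list:
    """Rebuild raw patient records from the two CSV frames."""
    by_patient: dict = {}
    for row in abx.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            RawAbxRecord(
                name_text=str(row.name_text),
                dose_text=str(row.dose_text),
                frequency_per_day=int(row.frequency_per_day),
                days=int(row.days),
            )
        )

    def _day(value) -> Optional[int]:
        return None if pd.isna(value) else int(value)

    cohort = []
    for row in patients.itertuples(index=False):
        cohort.append(
            RawPatientRecord(
                patient_id=str(row.patient_id),
                arm=str(row.arm),
                age=float(row.age),
                sex=str(row.sex),
                psm_weight=float(row.psm_weight),
                admission_day=_day(row.admission_day),
                covid_test_day=_day(row.covid_test_day),
                discharge_day=_day(row.discharge_day),
                icu_in_day=_day(row.icu_in_day),
                icu_out_day=_day(row.icu_out_day),
                survival_days=None if pd.isna(row.survival_days) else float(row.survival_days),
                pct_test_count=int(row.pct_test_count),
                antibiotic_records=tuple(by_patient.get(row.patient_id, ())),
                ethnicity=str(row.ethnicity),
                imd_decile=int(row.imd_decile),
                n_comorbidities=int(row.n_comorbidities),
            )
        )
    return cohort


def write_cohort(cohort: Iterable[RawPatientRecord], patients_path, abx_path) -> None:
    pf, af = cohort_to_frames(cohort)
    # %.17g round-trips doubles exactly through the CSV
    pf.to_csv(patients_path, index=False, float_format="%.17g")
    af.to_csv(abx_path, index=False)


def read_cohort(patients_path, abx_path) -> list:
    # round_trip parsing keeps write -> read an exact identity on floats
    patients = pd.read_csv(patients_path, float_precision="round_trip")
    abx_file = Path(abx_path)
    if abx_file.exists() and abx_file.stat().st_size > 0:
        abx = pd.read_csv(abx_path)
        if abx.empty:
            abx = pd.DataFrame(
                columns=["patient_id", "name_text", "dose_text", "frequency_per_day", "days"]
            )
    else:
        abx = pd.DataFrame(
            columns=["patient_id", "name_text", "dose_text", "frequency_per_day", "days"]
        )
    return frames_to_cohort(patients, abx)
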