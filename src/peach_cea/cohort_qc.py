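"""Length-of-stay derivation and cohort exclusion rules.

Total length of stay is the number of days between the later of the positive
COVID-19 test and hospital admission, and discharge; ICU length of stay is the
days between the later of the positive test and ICU admission, and ICU
discharge; general-ward days are the difference.  Records with missing ICU or
total length of stay or missing survival time, or with internally inconsistent
stays (ICU longer than total, or total longer than survival), are excluded as
erroneous rather than imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "EXCLUSION_RULES",
    "DerivedStays",
    "PatientRecord",
    "ExclusionLog",
    "derive_lengths_of_stay",
    "apply_exclusions",
]

#: Exclusion rules in attribution order (first matching rule claims a patient).
EXCLUSION_RULES = (
    "missing_icu_los",
    "missing_total_los",
    "missing_survival",
    "icu_gt_total",
    "total_gt_survival",
)


@dataclass(frozen=True)
class DerivedStays:
    """Lengths of stay derived from raw day offsets; ``None`` marks missing."""

    total_days: Optional[float]
    icu_days: Optional[float]
    ward_days: Optional[float]


@dataclass(frozen=True)
class PatientRecord:
    """One cleaned patient, invariants guaranteed by :func:`apply_exclusions`:
    ``icu_days <= total_days <= survival_days`` and
    ``ward_days = total_days - icu_days``, all non-negative."""

    patient_id: str
    arm: str
    age: float
    sex: str
    psm_weight: float
    ward_days: float
    icu_days: float
    total_days: float
    survival_days: float
    died_in_hospital: bool
    pct_test_count: int
    antibiotic_records: tuple = ()


@dataclass
class ExclusionLog:
    """Bookkeeping of exclusions.

    ``counts`` attributes each excluded patient to the first matching rule, so
    the counts sum to ``n_before - n_after``.  ``any_match`` counts every rule
    a patient violated (a record can appear under several rules), mirroring
    how overlapping violations would inflate per-rule totals.
    """

    counts: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})
    any_match: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})
    n_before: int = 0
    n_after: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())


def derive_lengths_of_stay(raw) -> DerivedStays:
    """Derive (total, ICU, ward) days from a raw record's day offsets.

    Missing inputs propagate missing flags; a negative derived stay (discharge
    before admission, or ICU discharge before entry) is treated as missing
    since such records are erroneous.  A patient with no recorded ICU episode
    has ``icu_days = 0``.
    """
    starts = [d for d in (raw.covid_test_day, raw.admission_day) if d is not None]
    if raw.discharge_day is None or not starts:
        total: Optional[float] = None
    else:
        total = float(raw.discharge_day - max(starts))
        if total < 0:
            total = None

    if raw.icu_in_day is None and raw.icu_out_day is None:
        icu: Optional[float] = 0.0
    elif raw.icu_in_day is None or raw.icu_out_day is None:
        icu = None
    else:
        icu_start = raw.icu_in_day
        if raw.covid_test_day is not None:
            icu_start = max(icu_start, raw.covid_test_day)
        icu = float(raw.icu_out_day - icu_start)
        if icu < 0:
            icu = None

    ward = None if (total is None or icu is None) else total - icu
    return DerivedStays(total_days=total, icu_days=icu, ward_days=ward)


def _first_violation(stays: DerivedStays, survival: Optional[float]) -> tuple:
    """Return (first matching rule or None, list of all matching rules)."""
    matches = []
    if stays.icu_days is None:
        matches.append("missing_icu_los")
    if stays.total_days is None:
        matches.append("missing_total_los")
    if survival is None:
        matches.append("missing_survival")
    if stays.icu_days is not None and stays.total_days is not None:
        if stays.icu_days > stays.total_days:
            matches.append("icu_gt_total")
    if survival is not None:
        for v in (stays.total_days, stays.icu_days):
            if v is not None and v > survival:
                matches.append("total_gt_survival")
                break
    return (matches[0] if matches else None), matches


def apply_exclusions(cohort: Iterable) -> tuple[list, ExclusionLog]:
    """Derive stays, drop erroneous records, and return clean patients + log.

    Each removal is attributed to the first matching rule in
    :data:`EXCLUSION_RULES` order; the log also carries any-match counts.
    In-hospital death is identified by survival time not exceeding the total
    stay.  Idempotent: running the output through again changes nothing.
    """
    raw_list = list(cohort)
    log = ExclusionLog(n_before=len(raw_list))
    clean = []
    for raw in raw_list:
        if isinstance(raw, PatientRecord):  # already clean
            clean.append(raw)
            continue
        stays = derive_lengths_of_stay(raw)
        first, matches = _first_violation(stays, raw.survival_days)
        for rule in matches:
            log.any_match[rule] += 1
        if first is not None:
            log.counts[first] += 1
            continue
        clean.append(
            PatientRecord(
                patient_id=raw.patient_id,
                arm=raw.arm,
                age=raw.age,
                sex=raw.sex,
                psm_weight=raw.psm_weight,
                ward_days=stays.ward_days,
                icu_days=stays.icu_days,
                total_days=stays.total_days,
                survival_days=float(raw.survival_days),
                died_in_hospital=raw.survival_days <= stays.total_days,
                pct_test_count=raw.pct_test_count,
                antibiotic_records=tuple(raw.antibiotic_records),
            )
        )
    log.n_after = len(clean)
    return clean, log
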