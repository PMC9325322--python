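"""Composite detection of hospitalization for bleeding adverse drug events.

A hospitalization counts as a bleeding ADE if any of four criteria fires
during the index stay of a patient who was exposed to an oral anticoagulant
in primary care in the 30 days before admission:

* **diagnosis** — a stay ICD-10 code matches the bleeding code set;
* **inr** — any INR strictly greater than 5 during the stay;
* **hemoglobin** — any hemoglobin at or below the sex-specific usual minimum
  (11 g/dL for men, 10 g/dL for women); an optional *delta* mode additionally
  requires a drop of ≥ 2 g/dL from the patient's pre-stay maximum;
* **antidote** — in-hospital administration of an anticoagulant antidote
  (vitamin K, idarucizumab, andexanet alfa or human prothrombin complex).

The result records every criterion that fired, not just the first.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Sequence

from .data_model import (
    AdministrationRecord,
    Analyte,
    HospitalStay,
    LabResult,
    Patient,
    Sex,
    normalize_atc,
)
from .knowledge_base import KnowledgeBase

#: Sex-specific minimum usual hemoglobin values (g/dL); at or below fires.
HB_THRESHOLD_G_DL = {Sex.M: 11.0, Sex.F: 10.0}

#: INR above which over-anticoagulation is flagged (strict inequality).
INR_THRESHOLD = 5.0

#: Required pre-stay drop for the optional hemoglobin delta mode (g/dL).
HB_DELTA_G_DL = 2.0


class AdeCriterion(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    INR = "inr"
    HEMOGLOBIN = "hemoglobin"
    ANTIDOTE = "antidote"


@dataclass(frozen=True)
class CriterionResult:
    criterion: AdeCriterion
    fired: bool
    evidence: tuple = ()  # codes, (date, value) pairs, or antidote ATC codes


@dataclass
class BleedingAdeResult:
    patient_id: str
    is_ade: bool
    criteria_fired: set[AdeCriterion] = field(default_factory=set)
    evidence: dict[AdeCriterion, tuple] = field(default_factory=dict)


def _stay_labs(
    labs: Sequence[LabResult], stay: HospitalStay, margin_days: int = 0
) -> list[LabResult]:
    lo = stay.admission_date - dt.timedelta(days=margin_days)
    hi = stay.discharge_date + dt.timedelta(days=margin_days)
    return [lab for lab in labs if lo <= lab.date <= hi]


def detect_by_diagnosis(stay: HospitalStay, kb: KnowledgeBase) -> CriterionResult:
    """Fires iff any stay diagnosis matches the bleeding ICD-10 code set.

    Matching is prefix-based (3–4 character roots allowed), dots ignored.
    """
    hits = tuple(
        d.icd10 for d in stay.diagnoses if kb.bleeding_icd10.matches_icd10(d.icd10)
    )
    return CriterionResult(AdeCriterion.DIAGNOSIS, bool(hits), hits)


def detect_by_inr(
    labs: Sequence[LabResult], stay: HospitalStay, margin_days: int = 0
) -> CriterionResult:
    """Fires iff any in-stay INR value strictly exceeds 5."""
    hits = tuple(
        (lab.date, lab.value)
        for lab in _stay_labs(labs, stay, margin_days)
        if lab.analyte is Analyte.INR and lab.value > INR_THRESHOLD
    )
    return CriterionResult(AdeCriterion.INR, bool(hits), hits)


def detect_by_hemoglobin(
    labs: Sequence[LabResult],
    sex: Sex,
    stay: HospitalStay,
    mode: str = "threshold",
    margin_days: int = 0,
) -> CriterionResult:
    """Fires iff any in-stay hemoglobin is at or below the usual minimum.

    ``mode="threshold"`` (default) applies the sex-specific cut-off alone
    (≤ 11 g/dL men, ≤ 10 g/dL women, inclusive).  ``mode="delta"``
    additionally requires a drop of ≥ 2 g/dL from the patient's maximum
    pre-stay hemoglobin; with no pre-stay value the threshold alone decides.
    """
    if mode not in ("threshold", "delta"):
        raise ValueError(f"mode must be 'threshold' or 'delta', got {mode!r}")
    if not isinstance(sex, Sex):
        raise ValueError(f"sex must be known for the hemoglobin criterion, got {sex!r}")
    threshold = HB_THRESHOLD_G_DL[sex]
    in_stay = [
        lab
        for lab in _stay_labs(labs, stay, margin_days)
        if lab.analyte is Analyte.HEMOGLOBIN
    ]
    hits = [(lab.date, lab.value) for lab in in_stay if lab.value <= threshold]
    if hits and mode == "delta":
        pre_stay = [
            lab.value
            for lab in labs
            if lab.analyte is Analyte.HEMOGLOBIN and lab.date < stay.admission_date
        ]
        if pre_stay:
            baseline = max(pre_stay)
            hits = [(d, v) for d, v in hits if baseline - v >= HB_DELTA_G_DL]
    return CriterionResult(AdeCriterion.HEMOGLOBIN, bool(hits), tuple(hits))


def detect_by_antidote(
    administrations: Sequence[AdministrationRecord],
    stay: HospitalStay,
    kb: KnowledgeBase,
) -> CriterionResult:
    """Fires iff any in-stay administration is an anticoagulant antidote."""
    hits = tuple(
        sorted(
            {
                normalize_atc(a.atc_code)
                for a in administrations
                if stay.admission_date <= a.admin_date <= stay.discharge_date
                and kb.antidote_atc.matches_atc(a.atc_code)
            }
        )
    )
    return CriterionResult(AdeCriterion.ANTIDOTE, bool(hits), hits)


def detect_bleeding_ade(
    patient: Patient,
    stay: HospitalStay,
    labs: Sequence[LabResult],
    administrations: Sequence[AdministrationRecord],
    kb: KnowledgeBase,
    mode: str = "threshold",
    lab_margin_days: int = 0,
) -> BleedingAdeResult:
    """Composite bleeding-ADE detection: disjunction of the four criteria.

    The study denominator is patients with primary-care anticoagulant
    exposure in the 30 days before the stay; the caller restricts the cohort,
    this function only evaluates the criteria.
    """
    results = [
        detect_by_diagnosis(stay, kb),
        detect_by_inr(labs, stay, lab_margin_days),
        detect_by_hemoglobin(labs, patient.sex, stay, mode, lab_margin_days),
        detect_by_antidote(administrations, stay, kb),
    ]
    fired = {r.criterion for r in results if r.fired}
    return BleedingAdeResult(
        patient_id=patient.patient_id,
        is_ade=bool(fired),
        criteria_fired=fired,
        evidence={r.criterion: r.evidence for r in results if r.fired},
    )
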