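"""Exposure screening: anticoagulant exposure, PIM status, DDI and PIM–DDI.

Screening runs per patient and per setting:

* *primary care* — drug eras built from community dispensings, intersected
  with the closed 30-day pre-admission window [admission − 30 d,
  admission − 1 d];
* *hospital* — drug eras built from in-hospital administrations, intersected
  with the index stay [admission, discharge].

A drug–drug interaction (DDI) event is an unordered pair of co-exposed drugs
(≥ 1 day of era overlap inside the setting window) matching a bleeding-risk
knowledge-base rule.  A PIM–DDI is a DDI whose anticoagulant member is itself
a potentially inappropriate medication in that setting — by age/renal Beers
condition for DOACs, or because the pair itself is one of the warfarin Beers
combinations.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import (
    DrugEra,
    HospitalStay,
    Patient,
    Setting,
    normalize_atc,
    pre_admission_window,
)
from .knowledge_base import (
    HarmonizedSeverity,
    KnowledgeBase,
    Mechanism,
    match_atc,
)


class PimTrigger(str, enum.Enum):
    AGE_GE_75 = "age_ge_75"
    AGE_GE_65_RENAL = "age_ge_65_renal"
    WARFARIN_COMBO = "warfarin_combo"


@dataclass(frozen=True)
class PimFinding:
    patient_id: str
    anticoag_atc: str
    setting: Setting
    triggered_rule: PimTrigger
    partner_atc: str | None = None  # set for warfarin Beers combinations


@dataclass(frozen=True)
class DdiEvent:
    patient_id: str
    drug_a_atc: str  # anticoagulant member when the pair contains one
    drug_b_atc: str
    setting: Setting
    severity: HarmonizedSeverity
    raw_theriaque_level: int | None
    mechanism: Mechanism
    overlap_start: dt.date
    overlap_end: dt.date
    is_pim_ddi: bool = False
    #: all drugs (anticoagulant + interacting partners) sharing ≥ 1 day of
    #: co-exposure with this event — triple combinations appear as pairwise
    #: events carrying the same combo context
    combo_context: tuple[str, ...] = ()

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.drug_a_atc, self.drug_b_atc})


# --------------------------------------------------------------------------
# window handling
# --------------------------------------------------------------------------


def setting_window(stay: HospitalStay, setting: Setting) -> tuple[dt.date, dt.date]:
    """Closed detection window for a setting relative to the index stay."""
    if setting is Setting.PRIMARY_CARE:
        return pre_admission_window(stay.admission_date)
    return (stay.admission_date, stay.discharge_date)


def _eras_in_window(
    eras: Iterable[DrugEra], setting: Setting, window: tuple[dt.date, dt.date]
) -> list[DrugEra]:
    lo, hi = window
    return [e for e in eras if e.setting is setting and e.overlaps(lo, hi)]


def _clip(era: DrugEra, window: tuple[dt.date, dt.date]) -> tuple[dt.date, dt.date]:
    return (max(era.start, window[0]), min(era.end, window[1]))


# --------------------------------------------------------------------------
# anticoagulant exposure
# --------------------------------------------------------------------------


def detect_anticoag_exposure(
    patient: Patient,
    eras: Sequence[DrugEra],
    stay: HospitalStay,
    kb: KnowledgeBase,
) -> dict[Setting, set[str]]:
    """Oral-anticoagulant ATC codes the patient is exposed to, per setting.

    Primary-care exposure requires an anticoagulant era intersecting the
    30-day pre-admission window; hospital exposure requires an
    administration era intersecting the stay.
    """
    out: dict[Setting, set[str]] = {Setting.PRIMARY_CARE: set(), Setting.HOSPITAL: set()}
    for setting in out:
        window = setting_window(stay, setting)
        for era in _eras_in_window(eras, setting, window):
            if kb.is_anticoagulant(era.atc_code):
                out[setting].add(era.atc_code)
    return out


def has_renal_impairment(
    stays: Sequence[HospitalStay], kb: KnowledgeBase, override: bool | None = None
) -> bool:
    """Renal impairment from look-back ICD-10 codes (default N18*, N19).

    ``override`` short-circuits for cohorts carrying an eGFR-based flag.
    """
    if override is not None:
        return override
    codes = kb.renal_impairment_icd10
    return any(codes.matches_icd10(d.icd10) for s in stays for d in s.diagnoses)


# --------------------------------------------------------------------------
# PIM classification
# --------------------------------------------------------------------------


def classify_pim(
    patient_id: str,
    anticoag_atc: str,
    setting: Setting,
    age_years: int,
    renal_impairment: bool,
    co_medication_eras: Sequence[DrugEra],
    kb: KnowledgeBase,
    window: tuple[dt.date, dt.date],
    anticoag_eras: Sequence[DrugEra] | None = None,
) -> PimFinding | None:
    """Apply the Beers PIM rule for one exposed anticoagulant.

    DOAC rules are age / age-plus-renal conditions; warfarin is a PIM iff a
    Beers partner era overlaps a warfarin era inside the setting window.
    Returns the most specific triggered rule, or ``None``.
    """
    if age_years < 65:
        raise ValueError(f"PIM classification requires age >= 65, got {age_years}")
    anticoag_atc = normalize_atc(anticoag_atc)
    rule = kb.pim_rule_for(anticoag_atc)
    if rule is None:
        return None
    if rule.min_age_alone is not None and age_years >= rule.min_age_alone:
        return PimFinding(patient_id, anticoag_atc, setting, PimTrigger.AGE_GE_75)
    if (
        rule.min_age_with_renal is not None
        and age_years >= rule.min_age_with_renal
        and renal_impairment
    ):
        return PimFinding(patient_id, anticoag_atc, setting, PimTrigger.AGE_GE_65_RENAL)
    if rule.partner_patterns:
        if anticoag_eras is None:
            anticoag_eras = [
                e for e in co_medication_eras if normalize_atc(e.atc_code) == anticoag_atc
            ]
        partners = sorted(
            {
                normalize_atc(e.atc_code)
                for e in co_medication_eras
                if normalize_atc(e.atc_code) != anticoag_atc
                and any(match_atc(normalize_atc(e.atc_code), p) for p in rule.partner_patterns)
                and any(
                    a.overlaps(max(e.start, window[0]), min(e.end, window[1]))
                    for a in anticoag_eras
                    if a.overlaps(*window) and e.overlaps(*window)
                )
            }
        )
        if partners:
            return PimFinding(
                patient_id, anticoag_atc, setting, PimTrigger.WARFARIN_COMBO, partners[0]
            )
    return None


# --------------------------------------------------------------------------
# DDI detection
# --------------------------------------------------------------------------


def detect_ddi(
    patient_eras: Sequence[DrugEra],
    setting: Setting,
    kb: KnowledgeBase,
    window: tuple[dt.date, dt.date],
) -> list[DdiEvent]:
    """Detect bleeding-risk DDI events for one patient in one setting.

    One event per unordered drug pair whose eras overlap (≥ 1 day) inside the
    window and that matches a bleeding-risk knowledge-base rule; when several
    rules match a pair the most severe one wins.  Events are deduplicated per
    (patient, pair) and are invariant to input record order.
    """
    eras = _eras_in_window(patient_eras, setting, window)
    if not eras:
        return []
    patient_id = eras[0].patient_id
    by_drug: dict[str, list[DrugEra]] = {}
    for e in eras:
        by_drug.setdefault(normalize_atc(e.atc_code), []).append(e)
    drugs = sorted(by_drug)

    events: dict[frozenset[str], DdiEvent] = {}
    for i, dx in enumerate(drugs):
        for dy in drugs[i + 1 :]:
            rules = kb.find_interactions(dx, dy)
            if not rules:
                continue
            overlap = _pair_overlap(by_drug[dx], by_drug[dy], window)
            if overlap is None:
                continue
            rule = max(
                rules,
                key=lambda r: (
                    r.harmonized_severity.rank,
                    -(r.severity_theriaque or 9),
                ),
            )
            a, b = _orient_pair(dx, dy, kb)
            events[frozenset({dx, dy})] = DdiEvent(
                patient_id=patient_id,
                drug_a_atc=a,
                drug_b_atc=b,
                setting=setting,
                severity=rule.harmonized_severity,
                raw_theriaque_level=rule.severity_theriaque,
                mechanism=rule.mechanism,
                overlap_start=overlap[0],
                overlap_end=overlap[1],
            )
    return _attach_combo_context(sorted(events.values(), key=lambda e: (e.drug_a_atc, e.drug_b_atc)))


def _pair_overlap(
    eras_x: Sequence[DrugEra],
    eras_y: Sequence[DrugEra],
    window: tuple[dt.date, dt.date],
) -> tuple[dt.date, dt.date] | None:
    """Earliest maximal co-exposure interval of two drugs inside the window."""
    best: tuple[dt.date, dt.date] | None = None
    for ex in eras_x:
        for ey in eras_y:
            lo = max(ex.start, ey.start, window[0])
            hi = min(ex.end, ey.end, window[1])
            if lo <= hi and (best is None or lo < best[0]):
                best = (lo, hi)
    return best


def _orient_pair(dx: str, dy: str, kb: KnowledgeBase) -> tuple[str, str]:
    """Put the anticoagulant member first, for stable reporting."""
    if kb.is_anticoagulant(dx):
        return dx, dy
    if kb.is_anticoagulant(dy):
        return dy, dx
    return tuple(sorted((dx, dy)))  # type: ignore[return-value]


def _attach_combo_context(events: list[DdiEvent]) -> list[DdiEvent]:
    """Group same-anticoagulant events sharing co-exposure days.

    Events for the same first drug whose overlap intervals intersect carry a
    shared combo context (sorted drug tuple), so triple combinations like
    warfarin–amiodarone–paracetamol can be reported from pairwise events.
    """
    out = []
    for ev in events:
        members = {ev.drug_a_atc, ev.drug_b_atc}
        for other in events:
            if other is ev or other.drug_a_atc != ev.drug_a_atc:
                continue
            if other.overlap_start <= ev.overlap_end and ev.overlap_start <= other.overlap_end:
                members.add(other.drug_b_atc)
        out.append(replace(ev, combo_context=tuple(sorted(members))))
    return out


# --------------------------------------------------------------------------
# PIM–DDI flagging
# --------------------------------------------------------------------------


def flag_pim_ddi(
    ddi_events: Sequence[DdiEvent],
    pim_findings: Sequence[PimFinding],
    kb: KnowledgeBase,
) -> list[DdiEvent]:
    """Set ``is_pim_ddi`` on DDI events of one patient/setting.

    True iff the event's anticoagulant member has a PIM finding in the same
    setting, or the pair itself triggers a warfarin Beers combination rule.
    """
    pim_keys = {(p.anticoag_atc, p.setting) for p in pim_findings}
    out = []
    for ev in ddi_events:
        anticoag = ev.drug_a_atc if kb.is_anticoagulant(ev.drug_a_atc) else None
        is_pim_ddi = False
        if anticoag is not None:
            if (anticoag, ev.setting) in pim_keys:
                is_pim_ddi = True
            else:
                rule = kb.pim_rule_for(anticoag)
                if rule is not None and any(
                    match_atc(ev.drug_b_atc, p) for p in rule.partner_patterns
                ):
                    is_pim_ddi = True
        out.append(replace(ev, is_pim_ddi=is_pim_ddi))
    return out


# --------------------------------------------------------------------------
# per-patient orchestration
# --------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """All screening findings for one patient."""

    patient_id: str
    exposures: dict[Setting, set[str]]
    pim_findings: list[PimFinding] = field(default_factory=list)
    ddi_events: list[DdiEvent] = field(default_factory=list)
    renal_impairment: bool = False

    def has_pim(self, setting: Setting) -> bool:
        return any(p.setting is setting for p in self.pim_findings)

    def has_ddi(self, setting: Setting) -> bool:
        return any(e.setting is setting for e in self.ddi_events)

    def has_pim_ddi(self, setting: Setting) -> bool:
        return any(e.setting is setting and e.is_pim_ddi for e in self.ddi_events)


def screen_patient(
    patient: Patient,
    eras: Sequence[DrugEra],
    stay: HospitalStay,
    lookback_stays: Sequence[HospitalStay],
    kb: KnowledgeBase,
    renal_override: bool | None = None,
) -> ScreenResult:
    """Run exposure, PIM, DDI and PIM–DDI detection for one patient."""
    renal = has_renal_impairment(list(lookback_stays) + [stay], kb, renal_override)
    exposures = detect_anticoag_exposure(patient, eras, stay, kb)
    age = patient.age_at_index
    pims: list[PimFinding] = []
    all_events: list[DdiEvent] = []
    for setting in (Setting.PRIMARY_CARE, Setting.HOSPITAL):
        window = setting_window(stay, setting)
        setting_eras = [e for e in eras if e.setting is setting]
        for atc in sorted(exposures[setting]):
            finding = classify_pim(
                patient.patient_id, atc, setting, age, renal, setting_eras, kb, window
            )
            if finding is not None:
                pims.append(finding)
        events = detect_ddi(eras, setting, kb, window)
        all_events.extend(flag_pim_ddi(events, pims, kb))
    return ScreenResult(
        patient_id=patient.patient_id,
        exposures=exposures,
        pim_findings=pims,
        ddi_events=all_events,
        renal_impairment=renal,
    )


def screen_cohort(
    patients: Sequence[Patient],
    eras: Sequence[DrugEra],
    index_stays: Mapping[str, HospitalStay],
    lookback_stays: Mapping[str, Sequence[HospitalStay]],
    kb: KnowledgeBase,
    renal_overrides: Mapping[str, bool] | None = None,
) -> dict[str, ScreenResult]:
    """Screen every patient with an index stay; returns results by patient."""
    eras_by_patient: dict[str, list[DrugEra]] = {}
    for e in eras:
        eras_by_patient.setdefault(e.patient_id, []).append(e)
    results: dict[str, ScreenResult] = {}
    for p in patients:
        stay = index_stays.get(p.patient_id)
        if stay is None:
            continue
        results[p.patient_id] = screen_patient(
            p,
            eras_by_patient.get(p.patient_id, []),
            stay,
            lookback_stays.get(p.patient_id, ()),
            kb,
            (renal_overrides or {}).get(p.patient_id),
        )
    return results


# --------------------------------------------------------------------------
# mechanism tabulation
# --------------------------------------------------------------------------


def tabulate_mechanisms(
    ddi_events: Iterable[DdiEvent], setting: Setting
) -> pd.DataFrame:
    """Patient-level mechanism frequency table for one setting.

    Each patient with ≥ 1 event is assigned a primary class — pharmacokinetic
    if any of their events is pharmacokinetic, else pharmacodynamic — and PD /
    PK percentages are computed over classed patients.  Pharmacokinetic
    subtype rows count patients with ≥ 1 event of the subtype, as a
    percentage of pharmacokinetic-class patients (a patient may contribute to
    several subtypes, so subtype percentages need not sum to 100).
    """
    events = [e for e in ddi_events if e.setting is setting]
    mechs_by_patient: dict[str, set[Mechanism]] = {}
    for e in events:
        mechs_by_patient.setdefault(e.patient_id, set()).add(e.mechanism)
    pk_patients = {p for p, ms in mechs_by_patient.items() if any(m.is_pharmacokinetic for m in ms)}
    pd_patients = set(mechs_by_patient) - pk_patients
    total = len(mechs_by_patient)

    rows = [
        {"mechanism": "PD", "n_patients": len(pd_patients),
         "percent": _pct(len(pd_patients), total)},
        {"mechanism": "PK", "n_patients": len(pk_patients),
         "percent": _pct(len(pk_patients), total)},
    ]
    for subtype in (
        Mechanism.PK_CYP2C9_2C19,
        Mechanism.PK_CYP3A4,
        Mechanism.PK_PGP,
        Mechanism.PK_CYP3A4_PGP,
    ):
        n = len({p for p, ms in mechs_by_patient.items() if subtype in ms})
        rows.append(
            {"mechanism": subtype.value, "n_patients": n, "percent": _pct(n, len(pk_patients))}
        )
    return pd.DataFrame(rows, columns=["mechanism", "n_patients", "percent"])


def _pct(count: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for empty denominators."""
    if denominator == 0:
        return 0.0
    import decimal

    return float(
        decimal.Decimal(100 * count / denominator).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )
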