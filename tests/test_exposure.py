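"""Anticoagulant exposure, PIM classification, DDI detection and mechanisms."""

import datetime as dt
import itertools

import numpy as np
import pytest

from pimddi.data_model import (
    Diagnosis,
    DiagnosisPosition,
    DispensingRecord,
    DrugEra,
    HospitalStay,
    Patient,
    Setting,
    Sex,
    StayType,
    build_drug_eras,
    pre_admission_window,
)
from pimddi.exposure import (
    DdiEvent,
    PimTrigger,
    classify_pim,
    detect_anticoag_exposure,
    detect_ddi,
    flag_pim_ddi,
    screen_patient,
    tabulate_mechanisms,
)
from pimddi.knowledge_base import HarmonizedSeverity, Mechanism

D = dt.date
ADM = D(2017, 3, 10)
STAY = HospitalStay("P1", ADM, D(2017, 3, 16), StayType.MEDICINE,
                    (Diagnosis("I48", DiagnosisPosition.PRINCIPAL),))
WINDOW = pre_admission_window(ADM)


def _patient(age=80, sex="M"):
    return Patient("P1", Sex(sex), D(ADM.year - age, ADM.month, 1), ADM)


def _era(atc, start_offset, n_days=30, setting=Setting.PRIMARY_CARE, pid="P1"):
    start = ADM - dt.timedelta(days=start_offset)
    return DrugEra(pid, atc, start, start + dt.timedelta(days=n_days - 1), setting)


class TestAnticoagExposure:
    def test_dispensing_14_days_pre_admission_exposes_rivaroxaban(self, kb):
        exposures = detect_anticoag_exposure(_patient(), [_era("B01AF01", 14)], STAY, kb)
        assert exposures[Setting.PRIMARY_CARE] == {"B01AF01"}
        assert exposures[Setting.HOSPITAL] == set()

    def test_dispensing_45_days_back_with_30_day_supply_reaches_window(self, kb):
        # era covers [admission-45, admission-16]: its tail is in the window
        exposures = detect_anticoag_exposure(_patient(), [_era("B01AA03", 45)], STAY, kb)
        assert exposures[Setting.PRIMARY_CARE] == {"B01AA03"}

    def test_era_ending_before_window_is_not_exposure(self, kb):
        exposures = detect_anticoag_exposure(_patient(), [_era("B01AA03", 70)], STAY, kb)
        assert exposures[Setting.PRIMARY_CARE] == set()

    def test_no_anticoagulant_records_no_exposure(self, kb):
        exposures = detect_anticoag_exposure(_patient(), [_era("N02BE01", 14)], STAY, kb)
        assert exposures == {Setting.PRIMARY_CARE: set(), Setting.HOSPITAL: set()}


class TestClassifyPim:
    def test_dabigatran_80_no_renal_is_age_pim(self, kb):
        f = classify_pim("P1", "B01AE07", Setting.PRIMARY_CARE, 80, False, [], kb, WINDOW)
        assert f is not None and f.triggered_rule is PimTrigger.AGE_GE_75

    def test_apixaban_70_without_renal_is_not_pim(self, kb):
        f = classify_pim("P1", "B01AF02", Setting.PRIMARY_CARE, 70, False, [], kb, WINDOW)
        assert f is None

    def test_apixaban_70_with_renal_is_pim(self, kb):
        f = classify_pim("P1", "B01AF02", Setting.PRIMARY_CARE, 70, True, [], kb, WINDOW)
        assert f is not None and f.triggered_rule is PimTrigger.AGE_GE_65_RENAL

    def test_warfarin_68_with_overlapping_amiodarone_is_combo_pim(self, kb):
        eras = [_era("B01AA03", 20), _era("C01BD01", 15)]
        f = classify_pim("P1", "B01AA03", Setting.PRIMARY_CARE, 68, False, eras, kb, WINDOW)
        assert f is not None
        assert f.triggered_rule is PimTrigger.WARFARIN_COMBO
        assert f.partner_atc == "C01BD01"

    def test_warfarin_without_partner_is_not_pim_at_any_age(self, kb):
        eras = [_era("B01AA03", 20)]
        assert classify_pim("P1", "B01AA03", Setting.PRIMARY_CARE, 90, True, eras, kb, WINDOW) is None

    def test_non_overlapping_partner_does_not_trigger_combo(self, kb):
        # amiodarone era entirely outside the pre-admission window
        eras = [_era("B01AA03", 20), _era("C01BD01", 100, n_days=10)]
        f = classify_pim("P1", "B01AA03", Setting.PRIMARY_CARE, 68, False, eras, kb, WINDOW)
        assert f is None

    def test_under_65_is_a_precondition_error(self, kb):
        with pytest.raises(ValueError, match="65"):
            classify_pim("P1", "B01AE07", Setting.PRIMARY_CARE, 60, False, [], kb, WINDOW)


class TestDetectDdi:
    def test_warfarin_paracetamol_overlap_is_a_level_3_event(self, kb):
        eras = [_era("B01AA03", 20), _era("N02BE01", 10)]
        events = detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW)
        assert len(events) == 1
        ev = events[0]
        assert ev.pair == {"B01AA03", "N02BE01"}
        assert ev.raw_theriaque_level == 3
        assert ev.severity is HarmonizedSeverity.MODERATE

    def test_rivaroxaban_amiodarone_is_level_2_dual_inhibition(self, kb):
        eras = [_era("B01AF01", 20), _era("C01BD01", 10)]
        events = detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW)
        assert len(events) == 1
        assert events[0].raw_theriaque_level == 2
        assert events[0].mechanism is Mechanism.PK_CYP3A4_PGP
        assert events[0].drug_a_atc == "B01AF01"  # anticoagulant member first

    def test_single_drug_patient_has_no_events(self, kb):
        assert detect_ddi([_era("B01AA03", 20)], Setting.PRIMARY_CARE, kb, WINDOW) == []

    def test_symmetric_under_pair_and_record_order(self, kb):
        eras = [_era("B01AA03", 20), _era("C01BD01", 10), _era("N02BE01", 5)]
        events_fwd = detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW)
        events_rev = detect_ddi(list(reversed(eras)), Setting.PRIMARY_CARE, kb, WINDOW)
        assert events_fwd == events_rev

    def test_triple_combination_shares_a_combo_context(self, kb):
        eras = [_era("B01AA03", 20), _era("C01BD01", 15), _era("N02BE01", 10)]
        events = detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW)
        assert len(events) == 2
        contexts = {e.combo_context for e in events}
        assert contexts == {("B01AA03", "C01BD01", "N02BE01")}

    def test_matches_brute_force_daily_coexposure_scan(self, kb):
        """Pairwise detection equals a day-by-day co-exposure scan."""
        rng = np.random.default_rng(42)
        drugs = ["B01AA03", "B01AF01", "C01BD01", "N02BE01", "B01AC06",
                 "N06AB10", "A02BC01"]
        for _ in range(25):
            eras = []
            for _ in range(rng.integers(1, 7)):
                atc = drugs[rng.integers(0, len(drugs))]
                eras.append(_era(atc, int(rng.integers(1, 70)), int(rng.integers(1, 40))))
            eras = build_drug_eras(
                [DispensingRecord("P1", e.atc_code, e.start, e.n_days) for e in eras], []
            )
            events = detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW)
            # oracle: enumerate days in the window, collect co-exposed KB pairs
            oracle_pairs = set()
            day = WINDOW[0]
            while day <= WINDOW[1]:
                active = {e.atc_code for e in eras if e.start <= day <= e.end}
                for a, b in itertools.combinations(sorted(active), 2):
                    if kb.find_interactions(a, b):
                        oracle_pairs.add(frozenset({a, b}))
                day += dt.timedelta(days=1)
            assert {e.pair for e in events} == oracle_pairs


class TestFlagPimDdi:
    def _events(self, kb, anticoag, partner, partner2=None):
        eras = [_era(anticoag, 20), _era(partner, 15)]
        if partner2:
            eras.append(_era(partner2, 10))
        return detect_ddi(eras, Setting.PRIMARY_CARE, kb, WINDOW), eras

    def test_pim_anticoagulant_makes_its_ddi_a_pim_ddi(self, kb):
        events, eras = self._events(kb, "B01AF01", "C01BD01")
        pim = classify_pim("P1", "B01AF01", Setting.PRIMARY_CARE, 80, False, eras, kb, WINDOW)
        flagged = flag_pim_ddi(events, [pim], kb)
        assert flagged[0].is_pim_ddi

    def test_non_pim_anticoagulant_ddi_is_not_pim_ddi(self, kb):
        events, eras = self._events(kb, "B01AF01", "C01BD01")
        # age 70, no renal impairment: rivaroxaban is not a PIM
        assert classify_pim("P1", "B01AF01", Setting.PRIMARY_CARE, 70, False, eras, kb, WINDOW) is None
        flagged = flag_pim_ddi(events, [], kb)
        assert not flagged[0].is_pim_ddi

    def test_paracetamol_on_warfarin_amiodarone_is_flagged_via_combo(self, kb):
        events, eras = self._events(kb, "B01AA03", "C01BD01", "N02BE01")
        pim = classify_pim("P1", "B01AA03", Setting.PRIMARY_CARE, 68, False, eras, kb, WINDOW)
        flagged = flag_pim_ddi(events, [pim], kb)
        assert len(flagged) == 2 and all(e.is_pim_ddi for e in flagged)


class TestContainment:
    def test_pim_ddi_patients_subset_of_pim_and_of_ddi(self, small_result):
        """Patients with >=1 PIM-DDI are contained in both parent sets."""
        for setting in (Setting.PRIMARY_CARE, Setting.HOSPITAL):
            pim = {p for p, s in small_result.screens.items() if s.has_pim(setting)}
            ddi = {p for p, s in small_result.screens.items() if s.has_ddi(setting)}
            both = {p for p, s in small_result.screens.items() if s.has_pim_ddi(setting)}
            assert both <= pim and both <= ddi


class TestMechanisms:
    @staticmethod
    def _event(pid, mech, setting=Setting.PRIMARY_CARE):
        return DdiEvent(
            pid, "B01AA03", "X99XX99", setting, HarmonizedSeverity.MODERATE, 3,
            mech, ADM, ADM,
        )

    def test_all_pd_events_leave_pk_subtypes_at_zero(self):
        events = [self._event(f"P{i}", Mechanism.PD) for i in range(5)]
        table = tabulate_mechanisms(events, Setting.PRIMARY_CARE).set_index("mechanism")
        assert table.loc["PD", "n_patients"] == 5
        assert table.loc["PK", "n_patients"] == 0
        assert (table.loc[["PK_CYP3A4_PGP", "PK_PGP", "PK_CYP3A4",
                           "PK_CYP2C9_2C19"], "n_patients"] == 0).all()

    def test_dual_inhibition_share_of_pharmacokinetic_patients(self):
        # 197 dual-inhibition patients among 803 pharmacokinetic patients
        events = [self._event(f"P{i}", Mechanism.PK_CYP3A4_PGP) for i in range(197)]
        events += [self._event(f"Q{i}", Mechanism.PK_CYP2C9_2C19) for i in range(606)]
        table = tabulate_mechanisms(events, Setting.PRIMARY_CARE).set_index("mechanism")
        assert table.loc["PK", "n_patients"] == 803
        assert table.loc["PK_CYP3A4_PGP", "percent"] == 24.5

    def test_planted_mechanism_mix_recovered_on_synthetic_cohort(self, small_result):
        events = [e for s in small_result.screens.values() for e in s.ddi_events]
        table = tabulate_mechanisms(events, Setting.PRIMARY_CARE).set_index("mechanism")
        n_classed = table.loc["PD", "n_patients"] + table.loc["PK", "n_patients"]
        assert n_classed > 0
        # dual CYP3A4+P-gp inhibition must be a substantial PK component
        assert table.loc["PK_CYP3A4_PGP", "n_patients"] > 0


def test_screen_patient_full_orchestration(kb):
    patient = _patient(age=80)
    disp = [
        DispensingRecord("P1", "B01AF01", ADM - dt.timedelta(days=14), 30),
        DispensingRecord("P1", "C01BD01", ADM - dt.timedelta(days=10), 30),
    ]
    eras = build_drug_eras(disp, [])
    screen = screen_patient(patient, eras, STAY, [], kb)
    assert screen.has_pim(Setting.PRIMARY_CARE)
    assert screen.has_ddi(Setting.PRIMARY_CARE)
    assert screen.has_pim_ddi(Setting.PRIMARY_CARE)
    assert not screen.has_ddi(Setting.HOSPITAL)
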