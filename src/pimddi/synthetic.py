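"""Synthetic linked cohort generator with full ground truth.

The generator emulates the structure of a linked French primary-care /
hospital data source: one year of community-pharmacy dispensings per patient,
an index hospital stay with ICD-10 coding, in-hospital drug administrations,
and INR / hemoglobin results — for an elderly cohort (≥ 65, ~70% ≥ 75,
median age ≈ 79) on oral anticoagulants.

Planting works top-down: per-patient PIM / DDI / PIM–DDI flags are drawn
first with the configured marginal prevalences (with PIM–DDI = PIM ∧ DDI),
then demographics, comorbidities, anticoagulant molecule and interacting
co-medications are synthesized so that the deterministic detection pipeline
recovers the flags exactly from the emitted records.  The bleeding outcome
is drawn from a planted logistic model on the realized covariates, with the
intercept calibrated by bisection so the expected marginal ADE rate hits the
target; each ADE patient is assigned one detection criterion (diagnosis,
INR, hemoglobin or antidote) and the corresponding evidence is written,
while non-ADE patients' records are kept below every criterion.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    AdministrationRecord,
    Analyte,
    Diagnosis,
    DiagnosisPosition,
    DispensingRecord,
    HospitalStay,
    LabResult,
    Patient,
    Sex,
    StayType,
)
from .pipeline import CohortTables

WARFARIN, APIXABAN, RIVAROXABAN, DABIGATRAN = "B01AA03", "B01AF02", "B01AF01", "B01AE07"

# interacting co-medication pools per anticoagulant; every entry must map to
# a knowledge-base interaction rule for that anticoagulant
_W_BEERS = {"C01BD01": 0.7, "J01EE01": 0.1, "J01MA02": 0.1, "J01FA09": 0.1}
_W_NON_BEERS = {
    "N02BE01": 0.40,  # paracetamol
    "C10AA05": 0.15,  # atorvastatin
    "H03AA01": 0.10,  # levothyroxine
    "B01AC06": 0.10,  # salicylate
    "N02AX02": 0.10,  # tramadol
    "N06AB10": 0.05,  # escitalopram
    "N06AB05": 0.05,  # paroxetine
    "N06AB04": 0.05,  # citalopram
}
_DOAC_PARTNERS = {
    RIVAROXABAN: {
        "C01BD01": 0.40, "C08DA01": 0.10, "C08DB01": 0.10, "C01BD07": 0.05,
        "L04AD01": 0.05, "B01AC06": 0.08, "N02AX02": 0.08, "M01AE01": 0.04,
        "N06AB10": 0.10,
    },
    APIXABAN: {
        "C01BD01": 0.45, "C08DA01": 0.12, "C08DB01": 0.12, "C01BD07": 0.06,
        "L04AD01": 0.05, "B01AC06": 0.08, "N02AX02": 0.08, "M01AE01": 0.04,
    },
    DABIGATRAN: {
        "C01BD01": 0.45, "C08DA01": 0.15, "C01BD07": 0.10,
        "B01AC06": 0.12, "N02AX02": 0.12, "M01AE01": 0.06,
    },
}

# non-interacting background medication pool (outside every KB pattern)
_NOISE_MEDS = (
    "A02BC01", "A10BA02", "C03CA01", "C07AB07", "C09AA05", "C08CA01",
    "N05BA01", "A11CC05", "R03AC02", "M04AA01",
)

_BLEEDING_DX = {"D68.3": 0.32, "R31": 0.19, "D62": 0.18, "K62.5": 0.13,
                "K92.1": 0.09, "R04.0": 0.09}
_NEUTRAL_DX = ("I48", "J18.9", "M17.1", "A09", "R55")
_COMORBIDITY_DX = {
    "history_of_stroke": "I63.9",
    "diabetes": "E11.9",
    "renal_disease": "N18.3",
    "liver_disease": "K74.6",
    "cancer": "C18.9",
    "hypertension": "I10",
}


@dataclass
class GeneratorConfig:
    """Study-level knobs of the synthetic cohort.

    Defaults are the cohort conditions the generator emulates: age structure
    (70.5% ≥ 75, median ≈ 79), sex split, primary-care anticoagulant shares,
    marginal PIM / DDI / PIM–DDI prevalences, a logistic bleeding-outcome
    model whose coefficients are the log odds ratios of the study design,
    a 17.1% target marginal ADE rate and the pathway mix across the
    primary-care → hospital transition.
    """

    n_patients: int = 1000
    seed: int = 0
    # cohort structure
    frac_pre_exposed: float = 0.693  # rest are in-hospital initiations
    frac_age_ge_75: float = 0.705
    age_tail_scale: float = 13.0  # exponential tail above 75, median ≈ 79 overall
    sex_male: float = 0.578
    anticoag_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            WARFARIN: 0.466, RIVAROXABAN: 0.239, APIXABAN: 0.183, DABIGATRAN: 0.116,
        }
    )
    # planted exposure-finding prevalences (primary care)
    target_pim: float = 0.229
    target_ddi: float = 0.472
    target_pim_ddi: float = 0.195
    extra_partner_prob: float = 0.35  # chance of each additional interacting partner
    triple_combo_prob: float = 0.5  # paracetamol on top of a warfarin Beers combo
    # covariates
    renal_prob: float = 0.15
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "history_of_stroke": 0.05,
            "previous_bleeding": 0.08,
            "diabetes": 0.25,
            "liver_disease": 0.03,
            "cancer": 0.05,
            "hypertension": 0.60,
        }
    )
    # planted logistic bleeding-outcome model (log odds ratios)
    outcome_log_or: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex_m": math.log(1.19),
            "age": math.log(1.03),  # per year
            "history_of_stroke": math.log(1.17),
            "previous_bleeding": math.log(4.23),
            "diabetes": math.log(1.29),
            "renal_disease": math.log(1.98),
            "liver_disease": math.log(1.72),
            "cancer": math.log(2.68),
            "hypertension": math.log(1.72),
            "pim": math.log(1.08),
            "ddi": math.log(1.15),
            "pim_ddi": math.log(1.23),
        }
    )
    target_ade_rate: float = 0.171
    ade_calibration_tol: float = 0.005  # on the expected marginal rate
    ade_criterion_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "diagnosis": 0.45, "inr": 0.26, "hemoglobin": 0.25, "antidote": 0.04,
        }
    )
    # pathway mix
    continued_prob: float = 0.486
    surgery_given_discontinued_no_ade: float = 0.387
    surgery_prob_other: float = 0.30
    # exposure history
    duration_class_shares: tuple[float, ...] = (0.065, 0.093, 0.082, 0.760)
    mean_noise_meds: float = 4.0
    mean_prior_stays: float = 0.8
    start_date: dt.date = dt.date(2016, 1, 1)

    def validate(self) -> None:
        for name, val in (
            ("frac_pre_exposed", self.frac_pre_exposed),
            ("frac_age_ge_75", self.frac_age_ge_75),
            ("sex_male", self.sex_male),
            ("target_pim", self.target_pim),
            ("target_ddi", self.target_ddi),
            ("target_pim_ddi", self.target_pim_ddi),
            ("renal_prob", self.renal_prob),
            ("target_ade_rate", self.target_ade_rate),
            ("continued_prob", self.continued_prob),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.target_pim_ddi > min(self.target_pim, self.target_ddi):
            raise ValueError("target_pim_ddi cannot exceed target_pim or target_ddi")
        for name, shares in (
            ("anticoag_shares", self.anticoag_shares.values()),
            ("ade_criterion_shares", self.ade_criterion_shares.values()),
            ("duration_class_shares", self.duration_class_shares),
        ):
            total = sum(shares)
            if not 0.95 <= total <= 1.05:
                raise ValueError(f"{name} must sum to 1 within tolerance, got {total}")


class CalibrationError(RuntimeError):
    """The target marginal ADE rate is unreachable for the planted model."""


@dataclass
class SyntheticCohort:
    tables: CohortTables
    ground_truth: pd.DataFrame  # one row per patient, indexed by patient_id
    config: GeneratorConfig


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _calibrate_intercept(
    linear_predictors: np.ndarray, target: float, tol: float
) -> float:
    """Bisect the intercept so the expected marginal event rate hits target."""
    if not 0.0 < target < 1.0:
        raise CalibrationError(f"target rate {target} must be strictly inside (0, 1)")

    def expected(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + linear_predictors)))))

    lo, hi = -50.0, 50.0
    if not expected(lo) <= target <= expected(hi):
        raise CalibrationError(f"target rate {target} unreachable for planted coefficients")
    for _ in range(200):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2
    if abs(expected(b0) - target) > tol:
        raise CalibrationError(
            f"calibration missed target {target} by more than {tol}"
        )
    return b0


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate the five raw tables plus per-patient ground truth.

    Running the detection pipeline on the emitted tables reproduces the
    planted PIM / DDI / PIM–DDI flags exactly (detection is deterministic
    given the written records), the pathway labels exactly, and the planted
    prevalences / ADE rate within sampling error.  Output is byte-identical
    for identical configuration and seed.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- joint flag probabilities (PIM–DDI = PIM ∧ DDI) ------------------
    p11 = cfg.target_pim_ddi
    p10 = cfg.target_pim - p11  # PIM only
    p01 = cfg.target_ddi - p11  # DDI only
    p00 = 1.0 - p11 - p10 - p01
    if min(p10, p01, p00) < 0:
        raise ValueError("inconsistent PIM/DDI/PIM-DDI targets")

    patients: list[Patient] = []
    dispensings: list[DispensingRecord] = []
    administrations: list[AdministrationRecord] = []
    stays: list[HospitalStay] = []
    labs: list[LabResult] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:06d}"
        pre_exposed = bool(rng.random() < cfg.frac_pre_exposed)
        age = _draw_age(rng, cfg)
        sex = Sex.M if rng.random() < cfg.sex_male else Sex.F
        admission = cfg.start_date + dt.timedelta(days=int(rng.integers(180, 540)))
        los = 1 + int(rng.poisson(6))
        discharge = admission + dt.timedelta(days=los)
        birth = dt.date(admission.year - age, admission.month, 1)

        comorb = {
            name: bool(rng.random() < p) for name, p in cfg.comorbidity_prevalence.items()
        }
        renal = bool(rng.random() < cfg.renal_prob)

        if pre_exposed:
            cell = rng.choice(4, p=[p00, p10, p01, p11])
            pim, ddi = bool(cell in (1, 3)), bool(cell in (2, 3))
        else:
            pim = ddi = False
        pim_ddi = pim and ddi

        drug, renal = _choose_drug(rng, cfg, pim, ddi, age, renal) if pre_exposed else (None, renal)
        partners = _choose_partners(rng, cfg, drug, pim, ddi) if pre_exposed else []

        row = {
            "patient_id": pid,
            "pre_exposed": pre_exposed,
            "drug": drug,
            "pim": pim,
            "ddi": ddi,
            "pim_ddi": pim_ddi,
            "age": age,
            "sex_m": int(sex is Sex.M),
            "renal_disease": int(renal),
            **{k: int(v) for k, v in comorb.items()},
        }
        truth_rows.append(row)
        patients.append(Patient(pid, sex, birth, admission))
        # records are written in a second pass, after the outcome draw
        row["_admission"] = admission
        row["_discharge"] = discharge
        row["_partners"] = partners
        row["_sex"] = sex

    truth = pd.DataFrame(truth_rows).set_index("patient_id", drop=False)

    # ---- outcome: planted logistic model on realized covariates ----------
    pre_mask = truth["pre_exposed"].to_numpy()
    lp = np.zeros(len(truth))
    for name, beta in cfg.outcome_log_or.items():
        lp += beta * truth[name].astype(float).to_numpy()
    b0 = _calibrate_intercept(lp[pre_mask], cfg.target_ade_rate, cfg.ade_calibration_tol)
    p_ade = np.where(pre_mask, 1.0 / (1.0 + np.exp(-(b0 + lp))), 0.0)
    ade = rng.random(len(truth)) < p_ade
    truth["linear_predictor"] = np.where(pre_mask, b0 + lp, np.nan)
    truth["p_ade"] = np.where(pre_mask, p_ade, np.nan)
    truth["ade"] = ade

    crit_names = list(cfg.ade_criterion_shares)
    crit_p = np.array([cfg.ade_criterion_shares[c] for c in crit_names], dtype=float)
    crit_p = crit_p / crit_p.sum()

    # ---- second pass: write records consistent with flags and outcome ----
    pathway_labels = []
    criteria = []
    for row in truth_rows:
        pid = row["patient_id"]
        admission, discharge = row["_admission"], row["_discharge"]
        sex = row["_sex"]
        is_ade = bool(truth.loc[pid, "ade"])
        criterion = (
            crit_names[int(rng.choice(len(crit_names), p=crit_p))] if is_ade else None
        )
        criteria.append(criterion)
        continued = bool(rng.random() < cfg.continued_prob) if row["pre_exposed"] else False

        # pathway label implied by what gets written
        if not row["pre_exposed"]:
            label = "initiated_in_hospital"
            surgery = rng.random() < cfg.surgery_prob_other
        elif continued:
            label = "continued"
            surgery = rng.random() < cfg.surgery_prob_other
        elif is_ade:
            label = "discontinued_bleeding"
            surgery = rng.random() < cfg.surgery_prob_other
        else:
            surgery = rng.random() < cfg.surgery_given_discontinued_no_ade
            label = "discontinued_surgery" if surgery else "discontinued_other"
        pathway_labels.append(label)

        # ---- primary-care dispensings -----------------------------------
        if row["pre_exposed"]:
            duration_days = (20, 60, 135, 300)[
                int(rng.choice(4, p=np.array(cfg.duration_class_shares)
                               / sum(cfg.duration_class_shares)))
            ]
            first = admission - dt.timedelta(days=duration_days)
            # the last dispensing must fall inside the pre-admission window
            last_offset = int(rng.integers(1, min(26, duration_days + 1)))
            d = admission - dt.timedelta(days=last_offset)
            while d >= first:
                dispensings.append(DispensingRecord(pid, row["drug"], d, 30))
                d -= dt.timedelta(days=30)
            for partner in row["_partners"]:
                off = int(rng.integers(1, 26))
                dispensings.append(
                    DispensingRecord(pid, partner, admission - dt.timedelta(days=off), 30)
                )
        for _ in range(int(rng.poisson(cfg.mean_noise_meds))):
            med = _NOISE_MEDS[int(rng.integers(0, len(_NOISE_MEDS)))]
            off = int(rng.integers(1, 360))
            dispensings.append(
                DispensingRecord(pid, med, admission - dt.timedelta(days=off), 30)
            )

        # ---- index stay diagnoses ---------------------------------------
        diagnoses: list[Diagnosis] = []
        if is_ade and criterion == "diagnosis":
            dx = _weighted_choice(rng, _BLEEDING_DX)
            diagnoses.append(Diagnosis(dx, DiagnosisPosition.PRINCIPAL))
        else:
            dx = _NEUTRAL_DX[int(rng.integers(0, len(_NEUTRAL_DX)))]
            diagnoses.append(Diagnosis(dx, DiagnosisPosition.PRINCIPAL))
        for name, code in _COMORBIDITY_DX.items():
            flag = row["renal_disease"] if name == "renal_disease" else row.get(name, 0)
            if flag:
                diagnoses.append(Diagnosis(code, DiagnosisPosition.ASSOCIATED))
        stays.append(
            HospitalStay(
                pid, admission, discharge,
                StayType.SURGERY if surgery else StayType.MEDICINE,
                tuple(diagnoses),
            )
        )

        # ---- look-back stays --------------------------------------------
        n_prior = int(rng.poisson(cfg.mean_prior_stays)) + int(bool(row.get("previous_bleeding")))
        for k in range(n_prior):
            prior_adm = admission - dt.timedelta(days=int(rng.integers(60, 330)))
            prior_dx = [Diagnosis(_NEUTRAL_DX[int(rng.integers(0, len(_NEUTRAL_DX)))],
                                  DiagnosisPosition.PRINCIPAL)]
            if k == 0 and row.get("previous_bleeding"):
                prior_dx = [Diagnosis("K92.2", DiagnosisPosition.PRINCIPAL)]
            stays.append(
                HospitalStay(pid, prior_adm, prior_adm + dt.timedelta(days=2),
                             StayType.MEDICINE, tuple(prior_dx))
            )

        # ---- labs --------------------------------------------------------
        lab_day = min(admission + dt.timedelta(days=1), discharge)
        if is_ade and criterion == "inr":
            labs.append(LabResult(pid, lab_day, Analyte.INR, round(5.5 + 2.5 * rng.random(), 1)))
        else:
            labs.append(
                LabResult(pid, lab_day, Analyte.INR,
                          round(min(4.5, max(0.9, rng.normal(2.3, 0.6))), 1))
            )
        hb_floor = 11.6 if sex is Sex.M else 10.6
        if is_ade and criterion == "hemoglobin":
            threshold = 11.0 if sex is Sex.M else 10.0
            labs.append(
                LabResult(pid, lab_day, Analyte.HEMOGLOBIN,
                          round(threshold - 0.3 - 2.0 * rng.random(), 1))
            )
        else:
            labs.append(
                LabResult(pid, lab_day, Analyte.HEMOGLOBIN,
                          round(max(hb_floor, rng.normal(13.2, 1.0)), 1))
            )

        # ---- in-hospital administrations ---------------------------------
        if is_ade and criterion == "antidote":
            administrations.append(AdministrationRecord(pid, "B02BA02", lab_day))
        hosp_anticoag = (
            row["drug"]
            if label == "continued"
            else (_weighted_choice(rng, dict(cfg.anticoag_shares))
                  if label == "initiated_in_hospital" else None)
        )
        if hosp_anticoag is not None:
            for day in range(min(4, (discharge - admission).days + 1)):
                administrations.append(
                    AdministrationRecord(pid, hosp_anticoag,
                                         admission + dt.timedelta(days=day))
                )
            if label == "continued":
                for partner in row["_partners"]:
                    administrations.append(AdministrationRecord(pid, partner, admission))
                    administrations.append(
                        AdministrationRecord(pid, partner, admission + dt.timedelta(days=1))
                    )

    truth["ade_criterion"] = criteria
    truth["pathway"] = pathway_labels
    truth = truth.drop(columns=["_admission", "_discharge", "_partners", "_sex"])

    tables = CohortTables(patients, dispensings, administrations, stays, labs)
    return SyntheticCohort(tables=tables, ground_truth=truth, config=cfg)


def _draw_age(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    if rng.random() < cfg.frac_age_ge_75:
        return min(99, 75 + int(rng.exponential(cfg.age_tail_scale)))
    return int(rng.integers(65, 75))


def _choose_drug(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    pim: bool,
    ddi: bool,
    age: int,
    renal: bool,
) -> tuple[str, bool]:
    """Pick an anticoagulant consistent with the planted flags.

    Warfarin PIM status arises only from a Beers combination (which is also a
    DDI), so a PIM-without-DDI patient must carry a DOAC; if their age/renal
    draw cannot support a DOAC Beers condition, renal impairment is forced on
    (the realized covariate is what enters the outcome model and the ground
    truth, so downstream recovery is unaffected).
    """
    shares = dict(cfg.anticoag_shares)
    if pim:
        candidates = {}
        if ddi:
            candidates[WARFARIN] = shares[WARFARIN]
        for doac, needs in ((RIVAROXABAN, 75), (DABIGATRAN, 75)):
            if age >= needs or renal:
                candidates[doac] = shares[doac]
        if renal:
            candidates[APIXABAN] = shares[APIXABAN]
        if not candidates:
            renal = True
            candidates = {d: shares[d] for d in (RIVAROXABAN, DABIGATRAN, APIXABAN)}
    else:
        candidates = {WARFARIN: shares[WARFARIN]}
        if not renal:
            candidates[APIXABAN] = shares[APIXABAN]
            if age < 75:
                candidates[RIVAROXABAN] = shares[RIVAROXABAN]
                candidates[DABIGATRAN] = shares[DABIGATRAN]
    return _weighted_choice(rng, candidates), renal


def _choose_partners(
    rng: np.random.Generator, cfg: GeneratorConfig, drug: str, pim: bool, ddi: bool
) -> list[str]:
    if not ddi:
        return []
    partners: list[str] = []
    if drug == WARFARIN:
        if pim:  # Beers combination: partner creates both the PIM and the DDI
            partners.append(_weighted_choice(rng, _W_BEERS))
            if rng.random() < cfg.triple_combo_prob:
                partners.append("N02BE01")  # classic triple with paracetamol
        else:
            partners.append(_weighted_choice(rng, _W_NON_BEERS))
        pool = _W_NON_BEERS
    else:
        pool = _DOAC_PARTNERS[drug]
        partners.append(_weighted_choice(rng, pool))
    while rng.random() < cfg.extra_partner_prob:
        extra = _weighted_choice(rng, pool)
        if extra not in partners:
            partners.append(extra)
        else:
            break
    return partners


# --------------------------------------------------------------------------
# frozen worked example
# --------------------------------------------------------------------------


def make_worked_example() -> tuple[CohortTables, pd.DataFrame]:
    """A fixed 12-patient cohort exercising every rule branch, hand-verified.

    Returns the raw tables and the expected findings (one row per patient:
    PIM trigger, DDI / PIM–DDI counts, ADE criteria, pathway label) frozen at
    fixture-authoring time.
    """
    d = dt.date
    adm, dis = d(2017, 3, 10), d(2017, 3, 16)
    in_window = d(2017, 2, 20)  # 18 days pre-admission; era covers the window

    patients, disp, admin, stays, labs = [], [], [], [], []
    expected = []

    def patient(pid, sex, age, stay_type="medicine", dx="I48:P"):
        patients.append(Patient(pid, Sex(sex), d(adm.year - age, adm.month, 1), adm))
        stays.append(
            HospitalStay(pid, adm, dis, StayType(stay_type),
                         tuple(_parse(dx)))
        )

    def _parse(spec):
        from .data_model import parse_diagnoses

        return parse_diagnoses(spec)

    def expect(pid, **kw):
        base = {"patient_id": pid, "pim_trigger": "", "n_ddi": 0, "n_pim_ddi": 0,
                "ade": False, "ade_criteria": "", "pathway": ""}
        base.update(kw)
        expected.append(base)

    # P01 dabigatran, 80 y: PIM by age; continued; no DDI, no ADE
    patient("P01", "M", 80)
    disp.append(DispensingRecord("P01", DABIGATRAN, in_window, 30))
    for k in range(3):
        admin.append(AdministrationRecord("P01", DABIGATRAN, adm + dt.timedelta(days=k)))
    expect("P01", pim_trigger="age_ge_75", pathway="continued")

    # P02 apixaban, 70 y with renal impairment: PIM (age 65 + renal); stopped
    patient("P02", "F", 70, dx="I48:P;N18.3:A")
    disp.append(DispensingRecord("P02", APIXABAN, in_window, 30))
    expect("P02", pim_trigger="age_ge_65_renal", pathway="discontinued_other")

    # P03 apixaban, 70 y, no renal: no PIM; surgical stay
    patient("P03", "M", 70, stay_type="surgery", dx="M16.1:P")
    disp.append(DispensingRecord("P03", APIXABAN, in_window, 30))
    expect("P03", pathway="discontinued_surgery")

    # P04 warfarin 68 y + amiodarone + paracetamol: Beers combo, triple
    # PIM-DDI, bleeding diagnosis (melena)
    patient("P04", "M", 68, dx="K92.1:P")
    for atc in (WARFARIN, "C01BD01", "N02BE01"):
        disp.append(DispensingRecord("P04", atc, in_window, 30))
    expect("P04", pim_trigger="warfarin_combo", n_ddi=2, n_pim_ddi=2,
           ade=True, ade_criteria="diagnosis", pathway="discontinued_bleeding")

    # P05 rivaroxaban 80 y + amiodarone: PIM by age, level-2 PIM-DDI; continued
    patient("P05", "F", 80)
    disp.append(DispensingRecord("P05", RIVAROXABAN, in_window, 30))
    disp.append(DispensingRecord("P05", "C01BD01", in_window, 30))
    for k in range(2):
        admin.append(AdministrationRecord("P05", RIVAROXABAN, adm + dt.timedelta(days=k)))
    expect("P05", pim_trigger="age_ge_75", n_ddi=1, n_pim_ddi=1, pathway="continued")

    # P06 rivaroxaban 70 y, no renal + amiodarone: DDI but no PIM
    patient("P06", "M", 70)
    disp.append(DispensingRecord("P06", RIVAROXABAN, in_window, 30))
    disp.append(DispensingRecord("P06", "C01BD01", in_window, 30))
    for k in range(2):
        admin.append(AdministrationRecord("P06", RIVAROXABAN, adm + dt.timedelta(days=k)))
    expect("P06", n_ddi=1, pathway="continued")

    # P07 warfarin 75 y + paracetamol: plain DDI; ADE by INR 6.1
    patient("P07", "M", 75)
    disp.append(DispensingRecord("P07", WARFARIN, in_window, 30))
    disp.append(DispensingRecord("P07", "N02BE01", in_window, 30))
    labs.append(LabResult("P07", adm + dt.timedelta(days=1), Analyte.INR, 6.1))
    expect("P07", n_ddi=1, ade=True, ade_criteria="inr", pathway="discontinued_bleeding")

    # P08 warfarin, female 77 y: ADE by hemoglobin 9.8 g/dL
    patient("P08", "F", 77)
    disp.append(DispensingRecord("P08", WARFARIN, in_window, 30))
    labs.append(LabResult("P08", adm + dt.timedelta(days=1), Analyte.HEMOGLOBIN, 9.8))
    expect("P08", ade=True, ade_criteria="hemoglobin", pathway="discontinued_bleeding")

    # P09 dabigatran 78 y: PIM by age; ADE by antidotes (vit K + idarucizumab)
    patient("P09", "M", 78)
    disp.append(DispensingRecord("P09", DABIGATRAN, in_window, 30))
    admin.append(AdministrationRecord("P09", "B02BA02", adm + dt.timedelta(days=1)))
    admin.append(AdministrationRecord("P09", "V03AB37", adm + dt.timedelta(days=1)))
    expect("P09", pim_trigger="age_ge_75", ade=True, ade_criteria="antidote",
           pathway="discontinued_bleeding")

    # P10 apixaban 82 y initiated in hospital only (renal impairment coded)
    patient("P10", "F", 82, dx="I48:P;N18.3:A")
    for k in range(3):
        admin.append(AdministrationRecord("P10", APIXABAN, adm + dt.timedelta(days=k)))
    expect("P10", pim_trigger="age_ge_65_renal", pathway="initiated_in_hospital")

    # P11 warfarin + clarithromycin (macrolide, not azithromycin): Beers combo
    patient("P11", "M", 69)
    disp.append(DispensingRecord("P11", WARFARIN, in_window, 30))
    disp.append(DispensingRecord("P11", "J01FA09", in_window, 30))
    expect("P11", pim_trigger="warfarin_combo", n_ddi=1, n_pim_ddi=1,
           pathway="discontinued_other")

    # P12 warfarin + azithromycin: excluded from the macrolide rule; INR at
    # exactly 5 does not fire (strict inequality); continued
    patient("P12", "F", 72)
    disp.append(DispensingRecord("P12", WARFARIN, in_window, 30))
    disp.append(DispensingRecord("P12", "J01FA10", in_window, 30))
    for k in range(2):
        admin.append(AdministrationRecord("P12", WARFARIN, adm + dt.timedelta(days=k)))
    labs.append(LabResult("P12", adm + dt.timedelta(days=1), Analyte.INR, 5.0))
    expect("P12", pathway="continued")

    tables = CohortTables(patients, disp, admin, stays, labs)
    return tables, pd.DataFrame(expected).set_index("patient_id")
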