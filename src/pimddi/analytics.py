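"""Descriptive tables, Charlson comorbidity score, cohort assembly and the
multivariable logistic regression of bleeding risk.

Prevalence is patient-level throughout: the prevalence of PIM / DDI / PIM–DDI
is the ratio of patients with at least one finding to the setting denominator
(all patients exposed to an oral anticoagulant in that setting).  The
"average number of DDI per patient" counts distinct interacting drug pairs
per patient over the full denominator.  Printed percentages are rounded
half-up to one decimal.

The logistic model regresses hospitalization for bleeding ADE on the
covariate set of the study design: sex, age (in years, untransformed),
history of stroke, previous bleeding event, diabetes, renal disease, liver
disease, cancer, hypertension, and the PIM / DDI / PIM–DDI indicators.
Odds ratios are exponentiated maximum-likelihood coefficients with Wald 95%
confidence intervals; p-values are raw (no multiple-testing correction).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ade import BleedingAdeResult
from .data_model import DispensingRecord, HospitalStay, Patient, Setting
from .exposure import ScreenResult, _pct

#: public alias: percentage of a count over a denominator, half-up, 1 decimal
percent = _pct
from .knowledge_base import KnowledgeBase

ANTICOAG_NAMES = {
    "B01AA03": "warfarin",
    "B01AF02": "apixaban",
    "B01AF01": "rivaroxaban",
    "B01AE07": "dabigatran",
}

#: ICD-10 roots for the comorbidity covariates of the bleeding-risk model.
COMORBIDITY_ICD10 = {
    "history_of_stroke": ("I63", "I64", "G45"),
    "diabetes": ("E10", "E11", "E12", "E13", "E14"),
    "renal_disease": ("N18", "N19"),
    "liver_disease": ("K70", "K71", "K72", "K73", "K74", "K75", "K76", "K77"),
    "cancer": ("C",),
    "hypertension": ("I10", "I11", "I12", "I13", "I15"),
}

#: Covariate order of the bleeding-risk logistic model.
LOGISTIC_COVARIATES = [
    "sex_m",
    "age",
    "history_of_stroke",
    "previous_bleeding",
    "diabetes",
    "renal_disease",
    "liver_disease",
    "cancer",
    "hypertension",
    "pim",
    "ddi",
    "pim_ddi",
]


# --------------------------------------------------------------------------
# prevalence (Table 2 structure)
# --------------------------------------------------------------------------


def prevalence_table(
    screens: Mapping[str, ScreenResult], setting: Setting, kb: KnowledgeBase
) -> pd.DataFrame:
    """Patient-level prevalence of anticoagulants, PIM, DDI and PIM–DDI.

    Rows: per-drug anticoagulant exposure; PIM total and per drug; DDI total,
    per drug, mean ± SD distinct pairs per patient and major-severity levels
    (Theriaque 1 and 2); PIM–DDI likewise.  Per-drug and total percentages
    are over the setting denominator (patients exposed in the setting);
    severity-level percentages are over patients with the measure.
    An empty denominator yields an empty table.
    """
    exposed = {
        pid: s for pid, s in screens.items() if s.exposures[setting]
    }
    n = len(exposed)
    if n == 0:
        return pd.DataFrame(columns=["measure", "drug", "count", "percent", "mean", "sd"])

    rows: list[dict] = [{"measure": "total", "drug": "", "count": n, "percent": 100.0}]

    def per_drug(measure: str, predicate) -> None:
        total_pids = {pid for pid, s in exposed.items() if predicate(s, None)}
        rows.append(
            {"measure": measure, "drug": "", "count": len(total_pids),
             "percent": _pct(len(total_pids), n)}
        )
        for atc, name in ANTICOAG_NAMES.items():
            pids = {pid for pid, s in exposed.items() if predicate(s, atc)}
            rows.append(
                {"measure": measure, "drug": name, "count": len(pids),
                 "percent": _pct(len(pids), n)}
            )

    per_drug(
        "anticoagulant",
        lambda s, atc: bool(s.exposures[setting]) if atc is None else atc in s.exposures[setting],
    )
    per_drug(
        "PIM",
        lambda s, atc: any(
            p.setting is setting and (atc is None or p.anticoag_atc == atc)
            for p in s.pim_findings
        ),
    )

    for measure, event_filter in (
        ("DDI", lambda e: True),
        ("PIM-DDI", lambda e: e.is_pim_ddi),
    ):
        per_drug(
            measure,
            lambda s, atc, f=event_filter: any(
                e.setting is setting
                and f(e)
                and (atc is None or e.drug_a_atc == atc)
                for e in s.ddi_events
            ),
        )
        counts = np.array(
            [
                len({e.pair for e in s.ddi_events if e.setting is setting and event_filter(e)})
                for s in exposed.values()
            ],
            dtype=float,
        )
        rows.append(
            {"measure": measure, "drug": "mean_per_patient",
             "count": int(counts.sum()), "percent": np.nan,
             "mean": round(float(counts.mean()), 1),
             "sd": round(float(counts.std(ddof=1)) if n > 1 else 0.0, 1)}
        )
        with_measure = {
            pid
            for pid, s in exposed.items()
            if any(e.setting is setting and event_filter(e) for e in s.ddi_events)
        }
        for level, label in ((1, "contraindicated_level_1"), (2, "not_recommended_level_2")):
            pids = {
                pid
                for pid, s in exposed.items()
                if any(
                    e.setting is setting and event_filter(e) and e.raw_theriaque_level == level
                    for e in s.ddi_events
                )
            }
            rows.append(
                {"measure": measure, "drug": label, "count": len(pids),
                 "percent": _pct(len(pids), len(with_measure))}
            )

    df = pd.DataFrame(rows, columns=["measure", "drug", "count", "percent", "mean", "sd"])
    return df


# --------------------------------------------------------------------------
# bleeding-ADE rates by group and combination (Table 4 structure)
# --------------------------------------------------------------------------


def bleeding_rates_by_group(
    screens: Mapping[str, ScreenResult],
    ade_results: Mapping[str, BleedingAdeResult],
    setting: Setting = Setting.PRIMARY_CARE,
    kb: KnowledgeBase | None = None,
) -> pd.DataFrame:
    """Hospitalization-for-bleeding rate per finding group and combination.

    For the PIM / DDI / PIM–DDI groups and for each interacting drug
    combination (pairs, and warfarin Beers-combination triples), the rate is
    the number of group patients with a bleeding ADE over the group size.
    A group of size 0 is emitted with a missing rate.
    """
    def ade(pid: str) -> bool:
        r = ade_results.get(pid)
        return bool(r and r.is_ade)

    cohort = {pid: s for pid, s in screens.items() if s.exposures[Setting.PRIMARY_CARE]}
    rows = []
    groups = {
        "all": set(cohort),
        "PIM": {p for p, s in cohort.items() if s.has_pim(setting)},
        "DDI": {p for p, s in cohort.items() if s.has_ddi(setting)},
        "PIM-DDI": {p for p, s in cohort.items() if s.has_pim_ddi(setting)},
    }
    for name, pids in groups.items():
        n_ade = sum(ade(p) for p in pids)
        rows.append(
            {"group": name, "combination": "", "n_patients": len(pids), "n_ade": n_ade,
             "rate_percent": _pct(n_ade, len(pids)) if pids else np.nan}
        )

    combos: dict[tuple[str, ...], set[str]] = {}
    combo_types: dict[tuple[str, ...], str] = {}
    for pid, s in cohort.items():
        for e in s.ddi_events:
            if e.setting is not setting:
                continue
            key = (e.drug_a_atc, e.drug_b_atc)
            combos.setdefault(key, set()).add(pid)
            combo_types[key] = "PIM-DDI" if e.is_pim_ddi else "DDI"
            # warfarin Beers triples: anticoagulant + combo partner + this drug
            if kb is not None and len(e.combo_context) > 2:
                rule = kb.pim_rule_for(e.drug_a_atc)
                if rule is not None and rule.partner_patterns:
                    from .knowledge_base import match_atc

                    for partner in e.combo_context:
                        if partner in (e.drug_a_atc, e.drug_b_atc):
                            continue
                        if any(match_atc(partner, p) for p in rule.partner_patterns):
                            tkey = (e.drug_a_atc, partner, e.drug_b_atc)
                            combos.setdefault(tkey, set()).add(pid)
                            combo_types[tkey] = "PIM-DDI"
    for key in sorted(combos):
        pids = combos[key]
        n_ade = sum(ade(p) for p in pids)
        label = "+".join(ANTICOAG_NAMES.get(c, c) for c in key)
        rows.append(
            {"group": combo_types[key], "combination": label,
             "n_patients": len(pids), "n_ade": n_ade,
             "rate_percent": _pct(n_ade, len(pids)) if pids else np.nan}
        )
    return pd.DataFrame(
        rows, columns=["group", "combination", "n_patients", "n_ade", "rate_percent"]
    )


# --------------------------------------------------------------------------
# Charlson comorbidity index
# --------------------------------------------------------------------------


def charlson_index(diagnoses_lookback: Iterable[str], kb: KnowledgeBase) -> int:
    """Charlson comorbidity score from look-back ICD-10 codes.

    Uses the Quan ICD-10 category mapping with the original Charlson weights
    shipped in the knowledge base.  Each category counts once regardless of
    how many codes map to it; hierarchical pairs (complicated vs.
    uncomplicated diabetes, moderate/severe vs. mild liver disease,
    metastatic tumor vs. any malignancy) count only the more severe member.
    """
    codes = [str(c).replace(".", "").strip().upper() for c in diagnoses_lookback]
    present: set[str] = set()
    for cat in kb.charlson:
        roots = [c.replace(".", "").upper() for c in cat.codes]
        if any(code.startswith(root) for code in codes for root in roots):
            present.add(cat.name)
    superseded = {
        cat.supersedes for cat in kb.charlson if cat.supersedes and cat.name in present
    }
    by_name = {cat.name: cat for cat in kb.charlson}
    return sum(by_name[name].weight for name in present - superseded)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------


def build_cohort(
    patients: Sequence[Patient],
    screens: Mapping[str, ScreenResult],
    ade_results: Mapping[str, BleedingAdeResult],
    index_stays: Mapping[str, HospitalStay],
    lookback_stays: Mapping[str, Sequence[HospitalStay]],
    dispensings: Sequence[DispensingRecord],
    kb: KnowledgeBase,
) -> pd.DataFrame:
    """Assemble one feature row per primary-care-exposed patient.

    This is the modelling denominator of the study: patients ≥ 65 who
    received an oral anticoagulant in primary care within 30 days before
    their index stay.  The outcome is the bleeding-ADE indicator; features
    cover demographics, look-back comorbidities, the Charlson score,
    polymedication, interaction burden, the PIM / DDI / PIM–DDI indicators,
    prior hospitalizations, anticoagulant molecule and exposure duration.
    """
    disp_by_patient: dict[str, list[DispensingRecord]] = {}
    for d in dispensings:
        disp_by_patient.setdefault(d.patient_id, []).append(d)

    rows = []
    for p in patients:
        screen = screens.get(p.patient_id)
        if screen is None or not screen.exposures[Setting.PRIMARY_CARE]:
            continue
        stay = index_stays[p.patient_id]
        prior = list(lookback_stays.get(p.patient_id, ()))
        lookback_dx = [d.icd10 for s in prior for d in s.diagnoses]
        index_dx = [d.icd10 for d in stay.diagnoses]
        all_dx = lookback_dx + index_dx
        ade = ade_results.get(p.patient_id)
        disp = disp_by_patient.get(p.patient_id, [])
        pc_exposed = screen.exposures[Setting.PRIMARY_CARE]

        row: dict = {
            "patient_id": p.patient_id,
            "outcome": int(bool(ade and ade.is_ade)),
            "age": p.age_at_index,
            "sex_m": int(p.sex.value == "M"),
        }
        for name, roots in COMORBIDITY_ICD10.items():
            row[name] = int(
                any(dx.replace(".", "").upper().startswith(r) for dx in all_dx for r in roots)
            )
        # renal impairment can also come from an eGFR-based override
        row["renal_disease"] = int(row["renal_disease"] or screen.renal_impairment)
        row["previous_bleeding"] = int(
            any(kb.bleeding_icd10.matches_icd10(dx) for dx in lookback_dx)
        )
        row["charlson"] = charlson_index(all_dx, kb)
        row["polymedication"] = len({d.atc_code for d in disp})
        row["n_anticoag_ddi"] = len(
            {e.pair for e in screen.ddi_events if e.setting is Setting.PRIMARY_CARE}
        )
        row["pim"] = int(screen.has_pim(Setting.PRIMARY_CARE))
        row["ddi"] = int(screen.has_ddi(Setting.PRIMARY_CARE))
        row["pim_ddi"] = int(screen.has_pim_ddi(Setting.PRIMARY_CARE))
        row["prior_hospitalizations"] = len(prior)
        for atc, name in ANTICOAG_NAMES.items():
            row[f"anticoag_{name}"] = int(atc in pc_exposed)
        row["exposure_duration_class"] = _exposure_duration_class(
            disp, kb, stay.admission_date
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _exposure_duration_class(
    dispensings: Sequence[DispensingRecord], kb: KnowledgeBase, admission: dt.date
) -> int:
    """Ordinal pre-admission anticoagulant exposure duration.

    0: ≤ 1 month, 1: 1–3 months, 2: 3–6 months, 3: > 6 months before
    admission, from the earliest anticoagulant dispensing in the look-back.
    """
    dates = [d.dispense_date for d in dispensings if kb.is_anticoagulant(d.atc_code)]
    if not dates:
        return 0
    months = (admission - min(dates)).days / 30.44
    if months <= 1:
        return 0
    if months <= 3:
        return 1
    if months <= 6:
        return 2
    return 3


# --------------------------------------------------------------------------
# logistic regression (Table 5 structure)
# --------------------------------------------------------------------------


class SeparationError(ValueError):
    """Perfect or quasi-perfect separation for a named covariate."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; lists the collinear columns."""


@dataclass
class OrTable:
    """Odds ratios with Wald 95% confidence intervals and p-values."""

    table: pd.DataFrame  # index: covariate; columns: or, ci_low, ci_high, p_value
    model: object = None

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.table.loc[covariate]


def fit_bleeding_logistic(
    cohort_rows: pd.DataFrame,
    covariates: Sequence[str] = tuple(LOGISTIC_COVARIATES),
    outcome: str = "outcome",
) -> OrTable:
    """Multivariable logistic regression of bleeding ADE by maximum likelihood.

    Returns an :class:`OrTable` with one row per covariate: odds ratio
    (exponentiated coefficient), Wald 95% CI bounds and p-value.

    Raises
    ------
    SingularDesignError
        If the design matrix is rank deficient (lists collinear columns).
    SeparationError
        On (quasi-)perfect separation, naming the offending covariate.
    """
    missing = [c for c in (*covariates, outcome) if c not in cohort_rows.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s): {', '.join(missing)}")
    y = cohort_rows[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    X = cohort_rows[list(covariates)].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        collinear = _collinear_columns(X, list(covariates))
        raise SingularDesignError(f"singular design; collinear column(s): {', '.join(collinear)}")

    _check_separation(cohort_rows, covariates, outcome)

    exog = sm.add_constant(cohort_rows[list(covariates)].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, exog).fit(disp=False, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = result.params.drop("const")
    conf = result.conf_int().drop(index="const")
    if np.abs(params).max() > 15:
        worst = params.abs().idxmax()
        raise SeparationError(f"perfect separation suspected for covariate {worst!r}")
    table = pd.DataFrame(
        {
            "or": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p_value": result.pvalues.drop("const"),
            "coef": params,
            "se": result.bse.drop("const"),
        }
    )
    return OrTable(table=table, model=result)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    out = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(name)
    return out or names


def _check_separation(
    df: pd.DataFrame, covariates: Sequence[str], outcome: str
) -> None:
    y = df[outcome]
    for name in covariates:
        x = df[name]
        if set(x.unique()) <= {0, 1} and x.nunique() == 2:
            tab = pd.crosstab(x, y)
            if tab.shape == (2, 2) and (tab.to_numpy() == 0).any():
                raise SeparationError(
                    f"perfect separation for covariate {name!r} "
                    f"(a zero cell in its 2x2 outcome table)"
                )
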