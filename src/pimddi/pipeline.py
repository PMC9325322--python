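"""End-to-end orchestration: tables in, findings / labels / cohort out.

Given the five linked tables, the pipeline builds drug eras, screens every
patient for anticoagulant exposure, PIM, DDI and PIM–DDI in both settings,
phenotypes bleeding ADEs on the modelling denominator (patients with
primary-care anticoagulant exposure in the 30 days before admission),
classifies treatment pathways and assembles the modelling cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import analytics
from .ade import BleedingAdeResult, detect_bleeding_ade
from .data_model import (
    AdministrationRecord,
    DispensingRecord,
    HospitalStay,
    LabResult,
    Patient,
    Setting,
    build_drug_eras,
    read_table,
    write_table,
)
from .exposure import ScreenResult, screen_cohort
from .knowledge_base import KnowledgeBase, load_kb
from .pathway import PathwayCategory, classify_cohort


@dataclass
class CohortTables:
    """The five linked longitudinal input tables."""

    patients: list[Patient]
    dispensings: list[DispensingRecord]
    administrations: list[AdministrationRecord]
    stays: list[HospitalStay]
    labs: list[LabResult]

    _KINDS = ("patients", "dispensing", "administrations", "stays", "labs")
    _ATTRS = ("patients", "dispensings", "administrations", "stays", "labs")

    @classmethod
    def read(cls, directory: str | Path) -> tuple["CohortTables", dict]:
        """Load all tables from a directory; returns tables plus reports."""
        directory = Path(directory)
        loaded, reports = {}, {}
        for kind, attr in zip(cls._KINDS, cls._ATTRS):
            records, report = read_table(directory / f"{kind}.csv", kind)
            loaded[attr] = records
            reports[kind] = report
        return cls(**loaded), reports

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind, attr in zip(self._KINDS, self._ATTRS):
            write_table(getattr(self, attr), directory / f"{kind}.csv", kind)


@dataclass
class PipelineResult:
    screens: dict[str, ScreenResult]
    ade_results: dict[str, BleedingAdeResult]
    pathway_labels: dict[str, PathwayCategory]
    cohort: pd.DataFrame  # one modelling row per primary-care-exposed patient
    index_stays: dict[str, HospitalStay]
    lookback_stays: dict[str, list[HospitalStay]]
    excluded_unexposed: list[str] = field(default_factory=list)


def split_stays(
    patients: Sequence[Patient], stays: Sequence[HospitalStay]
) -> tuple[dict[str, HospitalStay], dict[str, list[HospitalStay]]]:
    """Index stay (starting on the index admission date) vs. look-back stays."""
    index_stays: dict[str, HospitalStay] = {}
    lookback: dict[str, list[HospitalStay]] = {}
    index_dates = {p.patient_id: p.index_admission_date for p in patients}
    for s in stays:
        idx = index_dates.get(s.patient_id)
        if idx is None:
            continue
        if s.admission_date == idx:
            index_stays[s.patient_id] = s
        elif s.admission_date < idx:
            lookback.setdefault(s.patient_id, []).append(s)
    return index_stays, lookback


def run_pipeline(
    tables: CohortTables,
    kb: KnowledgeBase | None = None,
    ade_mode: str = "threshold",
) -> PipelineResult:
    """Run detection, phenotyping, pathway labelling and cohort assembly.

    Patients with zero anticoagulant exposure in both settings are excluded
    from all outputs (cohort inclusion), with their ids reported.
    """
    kb = kb if kb is not None else load_kb()
    eras = build_drug_eras(tables.dispensings, tables.administrations)
    index_stays, lookback = split_stays(tables.patients, tables.stays)
    screens = screen_cohort(tables.patients, eras, index_stays, lookback, kb)

    excluded = [
        pid
        for pid, s in screens.items()
        if not (s.exposures[Setting.PRIMARY_CARE] or s.exposures[Setting.HOSPITAL])
    ]
    screens = {pid: s for pid, s in screens.items() if pid not in set(excluded)}

    labs_by_patient: dict[str, list[LabResult]] = {}
    for lab in tables.labs:
        labs_by_patient.setdefault(lab.patient_id, []).append(lab)
    admin_by_patient: dict[str, list[AdministrationRecord]] = {}
    for a in tables.administrations:
        admin_by_patient.setdefault(a.patient_id, []).append(a)
    patients_by_id = {p.patient_id: p for p in tables.patients}

    ade_results: dict[str, BleedingAdeResult] = {}
    for pid, screen in screens.items():
        if not screen.exposures[Setting.PRIMARY_CARE]:
            continue  # the ADE denominator is primary-care-exposed patients
        ade_results[pid] = detect_bleeding_ade(
            patients_by_id[pid],
            index_stays[pid],
            labs_by_patient.get(pid, []),
            admin_by_patient.get(pid, []),
            kb,
            mode=ade_mode,
        )

    labels = classify_cohort(screens, ade_results, index_stays)
    cohort = analytics.build_cohort(
        [patients_by_id[pid] for pid in screens],
        screens,
        ade_results,
        index_stays,
        lookback,
        tables.dispensings,
        kb,
    )
    return PipelineResult(
        screens=screens,
        ade_results=ade_results,
        pathway_labels=labels,
        cohort=cohort,
        index_stays=index_stays,
        lookback_stays={pid: lookback.get(pid, []) for pid in screens},
        excluded_unexposed=excluded,
    )


def summarize_findings(result: PipelineResult) -> pd.DataFrame:
    """Per-patient findings summary (one row per screened patient).

    Columns: the PIM trigger of the first finding in either setting, the
    number of distinct primary-care DDI pairs and how many are PIM–DDI, the
    bleeding-ADE flag with its fired criteria, and the pathway label.
    """
    rows = []
    for pid in sorted(result.screens):
        s = result.screens[pid]
        ade = result.ade_results.get(pid)
        pc_events = [e for e in s.ddi_events if e.setting is Setting.PRIMARY_CARE]
        rows.append(
            {
                "patient_id": pid,
                "pim_trigger": s.pim_findings[0].triggered_rule.value if s.pim_findings else "",
                "n_ddi": len({e.pair for e in pc_events}),
                "n_pim_ddi": len({e.pair for e in pc_events if e.is_pim_ddi}),
                "ade": bool(ade and ade.is_ade),
                "ade_criteria": ";".join(
                    sorted(c.value for c in ade.criteria_fired)
                ) if ade else "",
                "pathway": result.pathway_labels[pid].value,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
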