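"""Domain types and CSV I/O for the linked primary-care / hospital tables.

The pipeline consumes five longitudinal tables, pre-linked on ``patient_id``:

* ``patients.csv`` — patient_id, sex, birth_year_month, index_admission_date
* ``dispensing.csv`` — community-pharmacy dispensings (patient_id, atc_code,
  dispense_date, supply_days)
* ``administrations.csv`` — in-hospital drug administrations (patient_id,
  atc_code, admin_date)
* ``stays.csv`` — hospital stays (patient_id, admission_date, discharge_date,
  stay_type, icd10_codes with ``:P``/``:A`` position suffixes, ``;``-joined)
* ``labs.csv`` — INR and hemoglobin results (patient_id, date, analyte, value)

All dates are ISO-8601 calendar dates and all exposure intervals are closed on
both ends.  A *drug era* is a derived maximal interval of continuous exposure
of one patient to one ATC code in one setting; primary-care eras are built
from dispensings (each covering ``supply_days`` days from the dispense date),
hospital eras from runs of administration dates.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# --------------------------------------------------------------------------
# constants / conventions
# --------------------------------------------------------------------------

#: Assumed coverage of one community-pharmacy dispensing, in days (monthly
#: dispensing convention in French community pharmacy; configurable per call
#: and per record via the supply_days column).
DEFAULT_SUPPLY_DAYS = 30

#: Length of the pre-admission exposure window, in days.  The window before an
#: admission on day D is the closed interval [D - 30, D - 1].
PRE_ADMISSION_WINDOW_DAYS = 30

#: Look-back horizon for comorbidities / prior hospitalizations, in days.
LOOKBACK_DAYS = 365

_FULL_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Setting(str, enum.Enum):
    PRIMARY_CARE = "primary_care"
    HOSPITAL = "hospital"


class StayType(str, enum.Enum):
    MEDICINE = "medicine"
    SURGERY = "surgery"


class Analyte(str, enum.Enum):
    INR = "INR"
    HEMOGLOBIN = "hemoglobin"


class DiagnosisPosition(str, enum.Enum):
    PRINCIPAL = "P"
    ASSOCIATED = "A"


def normalize_atc(code: str) -> str:
    """Uppercase and strip an ATC code (matching is case-insensitive)."""
    return str(code).strip().upper()


def is_full_atc(code: str) -> bool:
    """True iff *code* is a syntactically valid full 7-character ATC code."""
    return bool(_FULL_ATC_RE.match(code))


# --------------------------------------------------------------------------
# record types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: Sex
    birth_year_month: dt.date  # first day of the birth month
    index_admission_date: dt.date

    @property
    def age_at_index(self) -> int:
        """Completed years between birth month and the index admission."""
        b, d = self.birth_year_month, self.index_admission_date
        years = d.year - b.year
        if (d.month, d.day) < (b.month, b.day):
            years -= 1
        return years


@dataclass(frozen=True)
class DispensingRecord:
    patient_id: str
    atc_code: str
    dispense_date: dt.date
    supply_days: int = DEFAULT_SUPPLY_DAYS


@dataclass(frozen=True)
class AdministrationRecord:
    patient_id: str
    atc_code: str
    admin_date: dt.date


@dataclass(frozen=True)
class Diagnosis:
    icd10: str
    position: DiagnosisPosition


@dataclass(frozen=True)
class HospitalStay:
    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date
    stay_type: StayType
    diagnoses: tuple[Diagnosis, ...] = ()

    @property
    def length_of_stay(self) -> int:
        return (self.discharge_date - self.admission_date).days


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    date: dt.date
    analyte: Analyte
    value: float


@dataclass(frozen=True)
class DrugEra:
    """Maximal continuous exposure interval, closed on both ends."""

    patient_id: str
    atc_code: str
    start: dt.date
    end: dt.date
    setting: Setting

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        """≥ 1 day of intersection with the closed interval [start, end]."""
        return self.start <= end and start <= self.end


# --------------------------------------------------------------------------
# validation report
# --------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    line: int | None
    message: str


@dataclass
class ValidationReport:
    table: str
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, line: int | None, message: str) -> None:
        self.issues.append(ValidationIssue(line, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)


class TableLoadError(ValueError):
    """Structural load failure (missing file / missing required column)."""


_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_year_month", "index_admission_date"],
    "dispensing": ["patient_id", "atc_code", "dispense_date", "supply_days"],
    "administrations": ["patient_id", "atc_code", "admin_date"],
    "stays": ["patient_id", "admission_date", "discharge_date", "stay_type", "icd10_codes"],
    "labs": ["patient_id", "date", "analyte", "value"],
}

# plausibility bounds enforced at load
_LAB_BOUNDS = {Analyte.INR: (0.0, 20.0), Analyte.HEMOGLOBIN: (0.0, 25.0)}


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def _parse_month(value: str) -> dt.date:
    s = str(value).strip()
    if re.match(r"^\d{4}-\d{2}$", s):
        s += "-01"
    d = dt.date.fromisoformat(s)
    return d.replace(day=1)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------


def read_table(path: str | Path, kind: str):
    """Read and validate one input table.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma separated, header row).
    kind
        One of ``patients``, ``dispensing``, ``administrations``, ``stays``,
        ``labs``.

    Returns
    -------
    (records, report)
        Validated records (invariant-violating rows are excluded) and a
        :class:`ValidationReport` listing every excluded row with its line
        number.

    Raises
    ------
    TableLoadError
        If the file is missing or a required column is absent.
    """
    if kind not in _COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_COLUMNS)}")
    path = Path(path)
    if not path.exists():
        raise TableLoadError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise TableLoadError(f"{path}: missing required column(s) {', '.join(missing)}")
    report = ValidationReport(table=kind)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(_parse_row(kind, row._asdict()))
        except (ValueError, KeyError) as exc:
            report.add(line, str(exc))
    return records, report


def _parse_row(kind: str, row: dict):
    pid = str(row["patient_id"]).strip()
    if not pid:
        raise ValueError("empty patient_id")
    if kind == "patients":
        sex = Sex(str(row["sex"]).strip().upper())
        birth = _parse_month(row["birth_year_month"])
        index = _parse_date(row["index_admission_date"])
        if index <= birth:
            raise ValueError(f"index admission {index} not after birth month {birth}")
        p = Patient(pid, sex, birth, index)
        if p.age_at_index < 65:
            raise ValueError(f"age at index admission {p.age_at_index} < 65 (cohort inclusion)")
        return p
    if kind == "dispensing":
        atc = normalize_atc(row["atc_code"])
        if not is_full_atc(atc):
            raise ValueError(f"invalid ATC code {row['atc_code']!r}")
        supply = str(row.get("supply_days", "")).strip()
        supply_days = int(supply) if supply else DEFAULT_SUPPLY_DAYS
        if supply_days <= 0:
            raise ValueError(f"supply_days must be positive, got {supply_days}")
        return DispensingRecord(pid, atc, _parse_date(row["dispense_date"]), supply_days)
    if kind == "administrations":
        atc = normalize_atc(row["atc_code"])
        if not is_full_atc(atc):
            raise ValueError(f"invalid ATC code {row['atc_code']!r}")
        return AdministrationRecord(pid, atc, _parse_date(row["admin_date"]))
    if kind == "stays":
        admission = _parse_date(row["admission_date"])
        discharge = _parse_date(row["discharge_date"])
        if discharge < admission:
            raise ValueError(f"discharge {discharge} before admission {admission}")
        if (discharge - admission).days < 1:
            raise ValueError("infra-day stay (length of stay < 1 day) excluded")
        stay_type = StayType(str(row["stay_type"]).strip().lower())
        diagnoses = parse_diagnoses(row["icd10_codes"])
        return HospitalStay(pid, admission, discharge, stay_type, diagnoses)
    if kind == "labs":
        analyte = Analyte(str(row["analyte"]).strip())
        value = float(row["value"])
        lo, hi = _LAB_BOUNDS[analyte]
        if not (lo < value <= hi):
            raise ValueError(
                f"{analyte.value} value {value} outside plausibility bounds ({lo}, {hi}]"
            )
        return LabResult(pid, _parse_date(row["date"]), analyte, value)
    raise AssertionError(kind)


def parse_diagnoses(cell: str) -> tuple[Diagnosis, ...]:
    """Parse a ``;``-joined diagnosis cell like ``"I48:P;N18.3:A"``."""
    cell = str(cell).strip()
    if not cell:
        return ()
    out = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            code, pos = token.rsplit(":", 1)
            position = DiagnosisPosition(pos.strip().upper())
        else:
            code, position = token, DiagnosisPosition.ASSOCIATED
        out.append(Diagnosis(code.strip().upper(), position))
    return tuple(out)


def format_diagnoses(diagnoses: Iterable[Diagnosis]) -> str:
    return ";".join(f"{d.icd10}:{d.position.value}" for d in diagnoses)


def write_table(records: Sequence, path: str | Path, kind: str) -> None:
    """Write records back to the CSV dialect for *kind* (round-trip safe)."""
    rows: list[dict] = []
    for r in records:
        if kind == "patients":
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "sex": r.sex.value,
                    "birth_year_month": r.birth_year_month.strftime("%Y-%m"),
                    "index_admission_date": r.index_admission_date.isoformat(),
                }
            )
        elif kind == "dispensing":
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "atc_code": r.atc_code,
                    "dispense_date": r.dispense_date.isoformat(),
                    "supply_days": r.supply_days,
                }
            )
        elif kind == "administrations":
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "atc_code": r.atc_code,
                    "admin_date": r.admin_date.isoformat(),
                }
            )
        elif kind == "stays":
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "admission_date": r.admission_date.isoformat(),
                    "discharge_date": r.discharge_date.isoformat(),
                    "stay_type": r.stay_type.value,
                    "icd10_codes": format_diagnoses(r.diagnoses),
                }
            )
        elif kind == "labs":
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "date": r.date.isoformat(),
                    "analyte": r.analyte.value,
                    "value": r.value,
                }
            )
        else:
            raise ValueError(f"unknown table kind {kind!r}")
    pd.DataFrame(rows, columns=_COLUMNS[kind]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# drug-era construction
# --------------------------------------------------------------------------


def _merge_closed_intervals(
    intervals: list[tuple[dt.date, dt.date]], gap_tolerance_days: int
) -> list[tuple[dt.date, dt.date]]:
    """Union of closed day-intervals, merging runs separated by ≤ gap days."""
    intervals = sorted(intervals)
    merged: list[list[dt.date]] = []
    for start, end in intervals:
        if merged and (start - merged[-1][1]).days - 1 <= gap_tolerance_days:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_drug_eras(
    dispensings: Sequence[DispensingRecord],
    administrations: Sequence[AdministrationRecord],
    supply_days_default: int = DEFAULT_SUPPLY_DAYS,
    gap_tolerance_days: int = 0,
) -> list[DrugEra]:
    """Build non-overlapping drug eras per (patient, ATC code, setting).

    A dispensing on day *d* with supply *s* covers the closed interval
    [d, d + s − 1]; an administration covers its single day.  Per
    (patient, drug, setting), covered intervals are unioned, merging two
    intervals when the uncovered gap between them is at most
    ``gap_tolerance_days`` days.  The output is sorted by patient, drug,
    setting, start and is idempotent under re-application.
    """
    if gap_tolerance_days < 0:
        raise ValueError(f"gap_tolerance_days must be >= 0, got {gap_tolerance_days}")
    if supply_days_default <= 0:
        raise ValueError(f"supply_days_default must be positive, got {supply_days_default}")

    buckets: dict[tuple[str, str, Setting], list[tuple[dt.date, dt.date]]] = {}
    for rec in dispensings:
        supply = rec.supply_days if rec.supply_days else supply_days_default
        key = (rec.patient_id, normalize_atc(rec.atc_code), Setting.PRIMARY_CARE)
        buckets.setdefault(key, []).append(
            (rec.dispense_date, rec.dispense_date + dt.timedelta(days=supply - 1))
        )
    for rec in administrations:
        key = (rec.patient_id, normalize_atc(rec.atc_code), Setting.HOSPITAL)
        buckets.setdefault(key, []).append((rec.admin_date, rec.admin_date))

    eras: list[DrugEra] = []
    for (pid, atc, setting), intervals in buckets.items():
        for start, end in _merge_closed_intervals(intervals, gap_tolerance_days):
            eras.append(DrugEra(pid, atc, start, end, setting))
    eras.sort(key=lambda e: (e.patient_id, e.atc_code, e.setting.value, e.start))
    return eras


def eras_to_records(
    eras: Sequence[DrugEra],
) -> tuple[list[DispensingRecord], list[AdministrationRecord]]:
    """Express eras back as one covering record per era (idempotency helper)."""
    disp, adm = [], []
    for e in eras:
        if e.setting is Setting.PRIMARY_CARE:
            disp.append(DispensingRecord(e.patient_id, e.atc_code, e.start, e.n_days))
        else:
            adm.extend(
                AdministrationRecord(e.patient_id, e.atc_code, e.start + dt.timedelta(days=i))
                for i in range(e.n_days)
            )
    return disp, adm


def pre_admission_window(
    admission_date: dt.date, window_days: int = PRE_ADMISSION_WINDOW_DAYS
) -> tuple[dt.date, dt.date]:
    """Closed pre-admission window [admission − window, admission − 1]."""
    return (
        admission_date - dt.timedelta(days=window_days),
        admission_date - dt.timedelta(days=1),
    )
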