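"""Table I/O, validation and drug-era construction."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pimddi.data_model import (
    AdministrationRecord,
    DispensingRecord,
    Setting,
    TableLoadError,
    build_drug_eras,
    pre_admission_window,
    read_table,
    write_table,
)

D = dt.date


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    def test_well_formed_dispensing_rows_parse_cleanly(self, tmp_path):
        p = _write(
            tmp_path,
            "dispensing.csv",
            "patient_id,atc_code,dispense_date,supply_days\n"
            "P1,B01AA03,2017-01-01,30\n"
            "P1,B01AF02,2017-02-01,30\n"  # apixaban
            "P2,N02BE01,2017-01-15,30\n",
        )
        records, report = read_table(p, "dispensing")
        assert len(records) == 3 and report.ok
        assert records[1].atc_code == "B01AF02"

    def test_missing_column_is_a_load_error_naming_the_column(self, tmp_path):
        p = _write(tmp_path, "d.csv", "patient_id,dispense_date\nP1,2017-01-01\n")
        with pytest.raises(TableLoadError, match="atc_code"):
            read_table(p, "dispensing")

    def test_missing_file_is_a_load_error(self, tmp_path):
        with pytest.raises(TableLoadError, match="not found"):
            read_table(tmp_path / "nope.csv", "labs")

    def test_bad_atc_and_bad_date_reported_with_line_numbers(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "patient_id,atc_code,dispense_date,supply_days\n"
            "P1,NOTANATC,2017-01-01,30\n"
            "P2,B01AA03,not-a-date,30\n"
            "P3,B01AA03,2017-01-01,30\n",
        )
        records, report = read_table(p, "dispensing")
        assert len(records) == 1
        assert sorted(issue.line for issue in report.issues) == [2, 3]

    def test_discharge_before_admission_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "stays.csv",
            "patient_id,admission_date,discharge_date,stay_type,icd10_codes\n"
            "P1,2017-03-10,2017-03-01,medicine,I48:P\n",
        )
        records, report = read_table(p, "stays")
        assert records == [] and len(report) == 1
        assert "before admission" in report.issues[0].message

    def test_infra_day_stay_excluded(self, tmp_path):
        p = _write(
            tmp_path,
            "stays.csv",
            "patient_id,admission_date,discharge_date,stay_type,icd10_codes\n"
            "P1,2017-03-10,2017-03-10,medicine,I48:P\n",
        )
        records, report = read_table(p, "stays")
        assert records == [] and "infra-day" in report.issues[0].message

    def test_implausible_lab_value_rejected_with_message(self, tmp_path):
        p = _write(
            tmp_path,
            "labs.csv",
            "patient_id,date,analyte,value\nP1,2017-03-11,INR,25.0\nP1,2017-03-11,INR,2.5\n",
        )
        records, report = read_table(p, "labs")
        assert len(records) == 1 and "plausibility" in report.issues[0].message

    def test_under_65_patient_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "patients.csv",
            "patient_id,sex,birth_year_month,index_admission_date\n"
            "P1,M,1980-01,2017-03-10\n"
            "P2,F,1940-01,2017-03-10\n",
        )
        records, report = read_table(p, "patients")
        assert [r.patient_id for r in records] == ["P2"]
        assert "65" in report.issues[0].message


@pytest.mark.parametrize("kind", ["patients", "dispensing", "administrations", "stays", "labs"])
def test_write_read_round_trip(worked_example, tmp_path, kind):
    tables, _ = worked_example
    attr = {"dispensing": "dispensings"}.get(kind, kind)
    records = getattr(tables, attr if attr != "patients" else "patients")
    write_table(records, tmp_path / f"{kind}.csv", kind)
    back, report = read_table(tmp_path / f"{kind}.csv", kind)
    assert report.ok
    assert back == list(records)


class TestDrugEras:
    def test_two_contiguous_dispensings_merge_into_one_60_day_era(self):
        disp = [
            DispensingRecord("P1", "B01AA03", D(2017, 1, 1), 30),
            DispensingRecord("P1", "B01AA03", D(2017, 1, 31), 30),
        ]
        eras = build_drug_eras(disp, [], gap_tolerance_days=0)
        assert len(eras) == 1
        assert eras[0].n_days == 60
        assert eras[0].start == D(2017, 1, 1)

    def test_single_dispensing_era_spans_supply_days(self):
        eras = build_drug_eras([DispensingRecord("P1", "B01AF01", D(2017, 5, 1), 30)], [])
        assert len(eras) == 1 and eras[0].n_days == 30

    def test_admin_runs_split_by_gap_tolerance(self):
        d = D(2017, 3, 10)
        admins = [
            AdministrationRecord("P1", "B01AF02", d),
            AdministrationRecord("P1", "B01AF02", d + dt.timedelta(days=1)),
            AdministrationRecord("P1", "B01AF02", d + dt.timedelta(days=5)),
        ]
        eras = build_drug_eras([], admins, gap_tolerance_days=1)
        assert len(eras) == 2
        assert eras[0].n_days == 2 and eras[1].n_days == 1
        assert all(e.setting is Setting.HOSPITAL for e in eras)

    def test_negative_gap_tolerance_is_a_parameter_error(self):
        with pytest.raises(ValueError, match="gap_tolerance"):
            build_drug_eras([], [], gap_tolerance_days=-1)

    def test_era_construction_is_idempotent(self, small_cohort):
        from pimddi.data_model import eras_to_records

        tables = small_cohort.tables
        eras = build_drug_eras(tables.dispensings, tables.administrations)
        disp2, adm2 = eras_to_records(eras)
        again = build_drug_eras(disp2, adm2)
        assert again == eras

    @settings(max_examples=60, deadline=None)
    @given(
        records=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=120),  # start day offset
                st.integers(min_value=1, max_value=40),  # supply days
            ),
            min_size=1,
            max_size=12,
        ),
        gap=st.integers(min_value=0, max_value=5),
    )
    def test_era_days_equal_brute_force_day_set_union(self, records, gap):
        """Era day coverage must equal the union of per-record coverage days."""
        base = D(2017, 1, 1)
        disp = [
            DispensingRecord("P1", "B01AA03", base + dt.timedelta(days=o), s)
            for o, s in records
        ]
        eras = build_drug_eras(disp, [], gap_tolerance_days=gap)
        era_days = set()
        for e in eras:
            era_days |= {e.start + dt.timedelta(days=i) for i in range(e.n_days)}
        record_days = set()
        for o, s in records:
            record_days |= {base + dt.timedelta(days=o + i) for i in range(s)}
        if gap == 0:
            assert era_days == record_days
        else:
            # gap tolerance may only add bridging days, never remove coverage
            assert record_days <= era_days
        # eras for one (patient, drug, setting) never overlap
        sorted_eras = sorted(eras, key=lambda e: e.start)
        for a, b in zip(sorted_eras, sorted_eras[1:]):
            assert b.start > a.end


def test_pre_admission_window_is_closed_30_days():
    lo, hi = pre_admission_window(D(2017, 3, 10))
    assert lo == D(2017, 2, 8) and hi == D(2017, 3, 9)
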