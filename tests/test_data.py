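"""Trial data model: validation, unit costs, CSV round trips, result writing."""

import math

import pandas as pd
import pytest

import trialcea as t
from trialcea.data import (Arm, PATIENT_COLUMNS, Sex, TrialDataError,
                           patients_to_frame, read_patients, write_patients)
from conftest import make_patient


@pytest.mark.parametrize("field,expected", [
    ("emergency_visit", 189.0),
    ("outpatient_visit", 40.02),
    ("hospital_day", 310.17),
    ("surgical_hospital_day", 378.0),
    ("phone_call_nurse", 15.0),
    ("phone_call_physician", 21.47),
    ("contact_minutes", 8.0),
    ("nurse_salary_per_min", 0.21),
    ("physician_salary_per_min", 0.38),
    ("teccu_rental_per_patient_month", 3.99),
    ("leisure_hour", 9.18),
    ("visit_absence_hours", 3.3),
    ("wage_min", 12.04),
    ("wage_max", 25.23),
])
def test_default_unit_costs_match_published_table(unit_costs, field, expected):
    assert getattr(unit_costs, field) == expected


def test_wage_lookup_respects_bands_and_bounds(unit_costs):
    for sex in (Sex.M, Sex.F):
        for age in (18, 30, 44, 59, 80):
            w = unit_costs.wage_for(sex, age)
            assert unit_costs.wage_min <= w <= unit_costs.wage_max
    assert unit_costs.wage_for(Sex.M, 30) != unit_costs.wage_for(Sex.M, 50)


def test_unit_cost_yaml_round_trip_and_overrides(tmp_path, unit_costs):
    p = tmp_path / "uc.yaml"
    t.write_unit_costs(unit_costs, p)
    again = t.read_unit_costs(p)
    assert again == unit_costs
    (tmp_path / "o.yaml").write_text("outpatient_visit: 50.0\n")
    assert t.read_unit_costs(tmp_path / "o.yaml").outpatient_visit == 50.0


@pytest.mark.parametrize("yaml_text", [
    "leisure_hour: 0\n",              # must be > 0
    "emergency_visit: -1\n",          # negative rate
    "wage_table: {M: [50,50,50,50,50,50], F: [50,50,50,50,50,50]}\n",  # out of bounds
    "no_such_key: 1\n",               # unknown key
])
def test_invalid_unit_cost_config_rejected(tmp_path, yaml_text):
    p = tmp_path / "bad.yaml"
    p.write_text(yaml_text)
    with pytest.raises(TrialDataError):
        t.read_unit_costs(p)


def test_patient_csv_round_trip_preserves_values_and_missingness(tmp_path, trial_with_missing):
    path = tmp_path / "patients.csv"
    write_patients(trial_with_missing, path)
    back = read_patients(path)
    assert len(back) == len(trial_with_missing)
    assert patients_to_frame(back).equals(patients_to_frame(trial_with_missing))
    # the three week-24 dropouts survive as missing, not zeros
    n_missing = sum(1 for r in back if r.eq5d[24] is None)
    assert n_missing == 3
    assert all(r.arm == Arm.TECCU for r in back if r.eq5d[24] is None)


def test_read_patients_empty_file_with_header(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text(",".join(PATIENT_COLUMNS) + "\n")
    assert read_patients(p) == []


def test_blank_week24_utility_is_missing_not_error(tmp_path):
    rec = make_patient()
    df = patients_to_frame([rec])
    df.loc[0, "eq5d_w24"] = None
    p = tmp_path / "p.csv"
    df.to_csv(p, index=False)
    back = read_patients(p)
    assert back[0].eq5d[24] is None
    assert back[0].eq5d[0] == 0.8


@pytest.mark.parametrize("column,value,match", [
    ("arm", "PLACEBO", "unknown arm"),
    ("disease", "IBS", "unknown disease"),
    ("age_years", 12, "age_years"),
    ("eq5d_w0", 3.0, "eq5d"),
    ("work_impairment_pct_w12", 140, "percentage"),
])
def test_malformed_rows_rejected_with_location(tmp_path, column, value, match):
    df = patients_to_frame([make_patient()])
    df[column] = df[column].astype(object)
    df.loc[0, column] = value
    p = tmp_path / "bad.csv"
    df.to_csv(p, index=False)
    with pytest.raises(TrialDataError, match=match):
        read_patients(p)


def test_teccu_fields_forbidden_outside_teccu_arm():
    with pytest.raises(TrialDataError, match="telemonitoring"):
        make_patient(arm=Arm.CONTROL, teccu_contacts_nurse=2)


def test_write_results_manifest_and_determinism(tmp_path):
    tables = {
        "costs": pd.DataFrame({"a": [1.0, 2.0]}),
        "effects": pd.DataFrame({"b": [0.1]}),
        "draws": pd.DataFrame({"c": [3.0]}),
        "ceac": pd.DataFrame({"wtp": [0.0], "p": [0.5]}),
    }
    man1 = t.write_results(tables, tmp_path / "run1", metadata={"seed": 1})
    assert len(man1) >= 4 and "run_metadata" in man1
    t.write_results(tables, tmp_path / "run2", metadata={"seed": 1})
    for name in tables:
        b1 = (tmp_path / "run1" / f"{name}.csv").read_bytes()
        b2 = (tmp_path / "run2" / f"{name}.csv").read_bytes()
        assert b1 == b2


def test_write_results_empty_tables_metadata_only(tmp_path):
    man = t.write_results({}, tmp_path / "empty", metadata={"seed": 0})
    assert list(man) == ["run_metadata"]
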