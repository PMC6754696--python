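"""Cost model: category arithmetic, WPAI expansion, additivity/linearity."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

import trialcea as t
from trialcea.costs import (CostBreakdown, HEALTHCARE_FIELDS, PRODUCTIVITY_FIELDS,
                            absenteeism_cost, equipment_cost, healthcare_cost,
                            interval_expand, leisure_impairment_cost,
                            presenteeism_hours, telemonitoring_contact_cost,
                            total_cost, visit_absence_cost)
from trialcea.data import Arm, Disease, ResourceUse, TrialDataError
from conftest import make_patient


@pytest.mark.parametrize("minutes,salary,expected", [
    (8, 0.21, 1.68),   # nurse
    (8, 0.38, 3.04),   # physician
])
def test_telemonitoring_contact_rate_construction(minutes, salary, expected):
    assert telemonitoring_contact_cost(minutes, salary) == pytest.approx(expected)


@pytest.mark.parametrize("minutes,salary", [(0, 0.21), (8, 0), (-1, 0.5)])
def test_telemonitoring_contact_rejects_nonpositive(minutes, salary):
    with pytest.raises(TrialDataError):
        telemonitoring_contact_cost(minutes, salary)


def test_equipment_rental():
    assert equipment_cost(6, 3.99) == pytest.approx(23.94)
    assert equipment_cost(0, 3.99) == 0.0
    with pytest.raises(TrialDataError):
        equipment_cost(7, 3.99)


def test_healthcare_cost_categories(unit_costs):
    one_er = healthcare_cost(ResourceUse(emergency_visits=1), unit_costs)
    assert one_er.emergency == 189.0
    assert one_er.total == 189.0
    zero = healthcare_cost(ResourceUse(), unit_costs)
    assert zero.total == 0.0
    teccu = healthcare_cost(
        ResourceUse(teccu_contacts_nurse=2, teccu_contacts_physician=1), unit_costs)
    assert teccu.teccu_contacts == pytest.approx(2 * 1.68 + 1 * 3.04)  # 6.40


def test_absenteeism_and_presenteeism():
    assert absenteeism_cost(10, 12.04) == pytest.approx(120.40)
    assert absenteeism_cost(0, 25.0) == 0.0
    assert presenteeism_hours(50, 40) == 20.0
    assert presenteeism_hours(0, 40) == 0.0
    assert presenteeism_hours(100, 35) == 35.0


def test_visit_absence_and_leisure_impairment():
    assert visit_absence_cost(2, 15, 3.3) == pytest.approx(99.0)
    assert visit_absence_cost(0, 20, 3.3) == 0.0
    assert leisure_impairment_cost(0, 10, 9.18) == 0.0
    assert leisure_impairment_cost(100, 10, 9.18) == pytest.approx(91.80)
    assert leisure_impairment_cost(35, 20, 9.18) == pytest.approx(64.26)


def test_interval_expansion_is_piecewise_constant():
    assert interval_expand({12: 50.0, 24: 50.0}) == pytest.approx(24 * 50.0)
    assert interval_expand({12: 0.0, 24: 0.0}) == 0.0
    assert interval_expand({12: 50.0, 24: 0.0}) == pytest.approx(600.0)
    assert math.isnan(interval_expand({12: None, 24: 1.0}))


def test_total_cost_outpatient_worked_example(flat_wage_costs):
    rec = make_patient(outpatient_visits=6)
    b = total_cost(rec, flat_wage_costs)
    assert b.outpatient == pytest.approx(240.12)
    assert b.visit_absence == pytest.approx(6 * 3.3 * 15.0)  # 297.00
    assert b.total == pytest.approx(537.12)


def test_total_cost_all_zero_patients(unit_costs):
    assert total_cost(make_patient(), unit_costs).total == 0.0
    teccu = make_patient(arm=Arm.TECCU, teccu_months=6.0)
    assert total_cost(teccu, unit_costs).total == pytest.approx(23.94)


def test_total_cost_requires_imputed_record(unit_costs):
    rec = make_patient()
    rec.wpai[24].hours_missed = None
    with pytest.raises(TrialDataError, match="imputation"):
        total_cost(rec, unit_costs)
    rec2 = make_patient()
    rec2.resources.outpatient_visits = None
    with pytest.raises(TrialDataError, match="imputation"):
        total_cost(rec2, unit_costs)


def test_unemployed_patient_has_no_work_loss_costs(unit_costs):
    rec = make_patient(employed=False, outpatient_visits=2)
    b = total_cost(rec, unit_costs)
    assert b.absenteeism == 0.0 and b.presenteeism == 0.0
    assert b.visit_absence > 0  # visit time is valued for everyone


# -- property tests ---------------------------------------------------------

record_strategy = st.builds(
    make_patient,
    disease=st.sampled_from([Disease.CD, Disease.UC]),
    age=st.integers(18, 80),
    employed=st.booleans(),
    eq5d=st.tuples(st.floats(-1, 1), st.floats(-1, 1)),
    wpai_kwargs=st.fixed_dictionaries({
        "hours_missed": st.floats(0, 60),
        "hours_worked": st.floats(0.1, 60),
        "work_impairment_pct": st.floats(0, 100),
        "social_impairment_pct": st.floats(0, 100),
        "not_working": st.just(False),
    }),
    emergency_visits=st.integers(0, 5),
    outpatient_visits=st.integers(0, 10),
    hospital_days=st.integers(0, 20),
    surgical_hospital_days=st.integers(0, 10),
    phone_contacts_nurse=st.integers(0, 10),
    phone_contacts_physician=st.integers(0, 5),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(rec=record_strategy)
def test_breakdown_additivity(unit_costs, rec):
    b = total_cost(rec, unit_costs)
    hc = sum(getattr(b, f) for f in HEALTHCARE_FIELDS) + b.equipment
    prod = sum(getattr(b, f) for f in PRODUCTIVITY_FIELDS)
    assert b.total_healthcare == pytest.approx(hc)
    assert b.total_productivity == pytest.approx(prod)
    assert b.total == pytest.approx(hc + prod)
    assert all(getattr(b, f.name) >= 0 for f in dataclasses.fields(b))


def _scaled_costs(uc, k):
    money = ("emergency_visit", "outpatient_visit", "hospital_day",
             "surgical_hospital_day", "phone_call_nurse", "phone_call_physician",
             "nurse_salary_per_min", "physician_salary_per_min",
             "teccu_rental_per_patient_month", "leisure_hour")
    kwargs = {f: getattr(uc, f) * k for f in money}
    kwargs.update(wage_min=uc.wage_min * k, wage_max=uc.wage_max * k,
                  wage_table={s: tuple(r * k for r in v) for s, v in uc.wage_table.items()})
    return t.default_unit_costs(**kwargs)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rec=record_strategy, k=st.floats(0.5, 3.0))
def test_cost_linearity_in_unit_prices(unit_costs, rec, k):
    base = total_cost(rec, unit_costs)
    scaled = total_cost(rec, _scaled_costs(unit_costs, k))
    assert scaled.total == pytest.approx(k * base.total, rel=1e-9)
    assert scaled.absenteeism == pytest.approx(k * base.absenteeism, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rec=record_strategy,
       field=st.sampled_from(["emergency_visits", "outpatient_visits", "hospital_days",
                              "phone_contacts_nurse"]))
def test_cost_monotonicity_in_resource_use(unit_costs, rec, field):
    base = total_cost(rec, unit_costs).total
    more = rec.copy()
    setattr(more.resources, field, getattr(rec.resources, field) + 1)
    assert total_cost(more, unit_costs).total >= base
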