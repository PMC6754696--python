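"""Per-patient societal cost accounting over the 24-week trial horizon.

Three cost blocks, all valued in EUR at trial-period rates:

* health care — registry counts (emergency, outpatient, hospital and surgical
  days, telephone contacts) times official unit rates, plus telemonitoring
  contacts valued at provider minutes x salary per minute;
* equipment — flat platform rental per patient-month (telemonitoring arm);
* productivity and leisure — WPAI-derived absenteeism and presenteeism hours
  valued at the sex/age wage (human-capital approach, no discounting at this
  horizon), fixed time lost per in-person visit, patient time on telephone
  calls valued at the wage, and patient time on telemonitoring contacts valued
  at the leisure rate.

WPAI has a 7-day recall but is administered at weeks 0/12/24 only, so weekly
quantities are expanded piecewise-constant: the week-12 response covers weeks
1-12 and the week-24 response covers weeks 13-24.  The baseline response is a
covariate only and is never costed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

from .data import (PatientRecord, ResourceUse, TrialDataError, UnitCostTable,
                   TRIAL_MONTHS)

#: Weeks covered by each post-baseline assessment under piecewise-constant expansion.
INTERVAL_WEEKS = {12: 12.0, 24: 12.0}

HEALTHCARE_FIELDS = ("emergency", "outpatient", "hospitalization",
                     "surgery_hospitalization", "phone_calls", "teccu_contacts")
PRODUCTIVITY_FIELDS = ("absenteeism", "presenteeism", "visit_absence",
                       "call_absence", "leisure_teccu", "leisure_impairment")


@dataclass
class CostBreakdown:
    """Per-patient costs by category (EUR) with additive totals."""

    emergency: float = 0.0
    outpatient: float = 0.0
    hospitalization: float = 0.0
    surgery_hospitalization: float = 0.0
    phone_calls: float = 0.0
    teccu_contacts: float = 0.0
    equipment: float = 0.0
    absenteeism: float = 0.0
    presenteeism: float = 0.0
    visit_absence: float = 0.0
    call_absence: float = 0.0
    leisure_teccu: float = 0.0
    leisure_impairment: float = 0.0
    total_healthcare: float = 0.0
    total_productivity: float = 0.0
    total: float = 0.0

    def finalize(self) -> "CostBreakdown":
        """Recompute the three totals from the category fields."""
        self.total_healthcare = sum(getattr(self, f) for f in HEALTHCARE_FIELDS) + self.equipment
        self.total_productivity = sum(getattr(self, f) for f in PRODUCTIVITY_FIELDS)
        self.total = self.total_healthcare + self.total_productivity
        return self

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not (v >= 0 and math.isfinite(v)):
                raise TrialDataError(f"cost breakdown field {f.name} must be finite "
                                     f"and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def telemonitoring_contact_cost(minutes: float, salary_per_min: float) -> float:
    """Cost of one telemonitoring contact: provider minutes x salary per minute.

    There is no official rate for remote contacts, so the rate is constructed
    from the mean provider time per contact and the provider salary.
    """
    if not minutes > 0:
        raise TrialDataError(f"contact minutes must be > 0, got {minutes}")
    if not salary_per_min > 0:
        raise TrialDataError(f"salary_per_min must be > 0, got {salary_per_min}")
    return minutes * salary_per_min


def equipment_cost(months: float, rate: float) -> float:
    """Platform rental cost: patient-months x monthly rate."""
    if not 0 <= months <= TRIAL_MONTHS:
        raise TrialDataError(f"rental months must be in [0, {TRIAL_MONTHS}], got {months}")
    return months * rate


def healthcare_cost(resources: ResourceUse, costs: UnitCostTable) -> CostBreakdown:
    """Health-care (and equipment) cost fields from resource counts x unit rates."""
    b = CostBreakdown(
        emergency=resources.emergency_visits * costs.emergency_visit,
        outpatient=resources.outpatient_visits * costs.outpatient_visit,
        hospitalization=resources.hospital_days * costs.hospital_day,
        surgery_hospitalization=resources.surgical_hospital_days * costs.surgical_hospital_day,
        phone_calls=(resources.phone_contacts_nurse * costs.phone_call_nurse
                     + resources.phone_contacts_physician * costs.phone_call_physician),
        teccu_contacts=(
            resources.teccu_contacts_nurse
            * telemonitoring_contact_cost(costs.contact_minutes, costs.nurse_salary_per_min)
            + resources.teccu_contacts_physician
            * telemonitoring_contact_cost(costs.contact_minutes, costs.physician_salary_per_min)),
        equipment=equipment_cost(resources.teccu_months, costs.teccu_rental_per_patient_month),
    )
    return b.finalize()


def absenteeism_cost(hours_missed: float, wage: float) -> float:
    """Work hours missed (WPAI Q2) valued at the hourly wage."""
    if hours_missed < 0:
        raise TrialDataError(f"hours_missed must be >= 0, got {hours_missed}")
    return hours_missed * wage


def presenteeism_hours(work_impairment_pct: float, hours_worked: float) -> float:
    """Effective hours lost while at work: Q5 impairment x Q4 hours worked.

    Capped at hours actually worked (100% impairment cannot lose more time
    than was worked).
    """
    if not 0 <= work_impairment_pct <= 100:
        raise TrialDataError(
            f"work_impairment_pct must be in [0, 100], got {work_impairment_pct}")
    if hours_worked < 0:
        raise TrialDataError(f"hours_worked must be >= 0, got {hours_worked}")
    return min(work_impairment_pct / 100.0 * hours_worked, hours_worked)


def visit_absence_cost(n_visits: float, wage: float, hours_per_visit: float) -> float:
    """Work time lost attending in-person visits: visits x hours-per-visit x wage."""
    if n_visits < 0:
        raise TrialDataError(f"n_visits must be >= 0, got {n_visits}")
    return n_visits * hours_per_visit * wage


def leisure_impairment_cost(social_impairment_pct: float, leisure_hours_base: float,
                            leisure_rate: float) -> float:
    """Leisure time lost to activity impairment (WPAI Q6) valued at the leisure rate."""
    if not 0 <= social_impairment_pct <= 100:
        raise TrialDataError(
            f"social_impairment_pct must be in [0, 100], got {social_impairment_pct}")
    if leisure_hours_base < 0:
        raise TrialDataError(f"leisure_hours_base must be >= 0, got {leisure_hours_base}")
    return social_impairment_pct / 100.0 * leisure_hours_base * leisure_rate


def interval_expand(weekly_values: dict[int, float | None]) -> float:
    """Expand weekly (7-day recall) quantities at weeks 12/24 to a 24-week total.

    Piecewise-constant: the week-12 value covers weeks 1-12, the week-24 value
    covers weeks 13-24.  The baseline value is ignored.  Returns ``nan`` when
    any covered assessment is missing (imputation must run first).
    """
    total = 0.0
    for week, n_weeks in INTERVAL_WEEKS.items():
        v = weekly_values.get(week)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return math.nan
        total += n_weeks * v
    return total


def _weekly_absence_hours(rec: PatientRecord, week: int) -> float | None:
    wp = rec.wpai[week]
    if not rec.employed or wp.not_working:
        return 0.0
    return wp.hours_missed


def _weekly_presenteeism_hours(rec: PatientRecord, week: int) -> float | None:
    wp = rec.wpai[week]
    if not rec.employed or wp.not_working:
        return 0.0
    if wp.work_impairment_pct is None or wp.hours_worked is None:
        return None
    return presenteeism_hours(wp.work_impairment_pct, wp.hours_worked)


def _weekly_social_impairment(rec: PatientRecord, week: int) -> float | None:
    return rec.wpai[week].social_impairment_pct


def total_cost(rec: PatientRecord, costs: UnitCostTable) -> CostBreakdown:
    """Full societal cost breakdown for one (fully observed or imputed) patient."""
    wage = costs.wage_for(rec.sex, rec.age_years)
    if not rec.resources.is_complete:
        raise TrialDataError(
            f"patient {rec.patient_id}: missing resource counts; run imputation before costing")
    b = healthcare_cost(rec.resources, costs)

    absent_hours = interval_expand({w: _weekly_absence_hours(rec, w) for w in (12, 24)})
    pres_hours = interval_expand({w: _weekly_presenteeism_hours(rec, w) for w in (12, 24)})
    social = interval_expand({w: _weekly_social_impairment(rec, w) for w in (12, 24)})
    if any(math.isnan(v) for v in (absent_hours, pres_hours, social)):
        raise TrialDataError(
            f"patient {rec.patient_id}: missing WPAI data; run imputation before costing")

    b.absenteeism = absenteeism_cost(absent_hours, wage)
    b.presenteeism = absenteeism_cost(pres_hours, wage)
    in_person = rec.resources.outpatient_visits + rec.resources.emergency_visits
    b.visit_absence = visit_absence_cost(in_person, wage, costs.visit_absence_hours)
    n_calls = rec.resources.phone_contacts_nurse + rec.resources.phone_contacts_physician
    # patient time on provider phone calls, assumed during working hours
    b.call_absence = n_calls * costs.patient_phone_minutes / 60.0 * wage
    n_teccu = rec.resources.teccu_contacts_nurse + rec.resources.teccu_contacts_physician
    # platform contacts happen out of office hours -> leisure valuation
    b.leisure_teccu = n_teccu * costs.teccu_patient_minutes / 60.0 * costs.leisure_hour
    # Q6 social-activity impairment over a configurable weekly leisure base;
    # the 24-week total of (weekly pct) is `social`, so divide by 100 once.
    b.leisure_impairment = (social / 100.0) * costs.leisure_hours_weekly * costs.leisure_hour

    b.finalize()
    if costs.inflation_multiplier != 1.0:
        for f in dc_fields(b):
            setattr(b, f.name, getattr(b, f.name) * costs.inflation_multiplier)
    b.validate()
    return b


def cost_frame(records, costs: UnitCostTable):
    """Cost breakdowns for a collection of records as a DataFrame (one row each)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "arm": rec.arm.value}
        row.update(total_cost(rec, costs).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
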