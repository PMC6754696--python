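"""Published group-level summaries of the three-arm IBD telemonitoring trial.

The trial compared Web telemonitoring (TECCU), nurse-assisted telephone care
(NT), and standard face-to-face care (CONTROL) over 24 weeks in 63 patients
with complex inflammatory bowel disease (21 per arm).  Patient-level data were
never released; what is public are arm-level summaries: unit costs, per-patient
resource-use and cost means/SDs per category, remission counts at baseline and
week 24, weeks in remission, and EQ-5D utility summaries.

This module freezes those summaries as a machine-readable fixture.  It is the
calibration target for :mod:`trialcea.simulate` and the input for the worked
arithmetic examples (ICERs from mean differences, gained QALYs from median
utility improvements).
"""

from __future__ import annotations

from typing import Any

#: EUR -> USD factor used throughout the published report
#: (ratio of every printed €/US$ pair, e.g. €20,000 -> US $21,893).
EUR_TO_USD = 1.09465

#: Unit costs per resource (EUR), trial-period Spanish official rates.
UNIT_COSTS: dict[str, float] = {
    "emergency_visit": 189.0,          # per visit
    "outpatient_visit": 40.02,         # per visit
    "hospital_day": 310.17,            # per day
    "surgical_hospital_day": 378.0,    # per day
    "phone_call_nurse": 15.0,          # per contact
    "phone_call_physician": 21.47,     # per contact
    "contact_minutes": 8.0,            # provider minutes per telemonitoring contact
    "nurse_salary_per_min": 0.21,      # €/min
    "physician_salary_per_min": 0.38,  # €/min
    "teccu_rental_per_patient_month": 3.99,
    "wage_min": 12.04,                 # €/h, bounds of the sex/age wage table
    "wage_max": 25.23,
    "leisure_hour": 9.18,              # €/h of leisure time
    "visit_absence_hours": 3.3,        # hours of work lost per in-person visit
}

#: Derived telemonitoring contact rates (8 min x salary/min).
TECCU_CONTACT_COST = {"nurse": 1.68, "physician": 3.04}

#: Per-arm mean (SD) resource units over the 24-week horizon.
RESOURCE_UNITS: dict[str, dict[str, tuple[float, float]]] = {
    "CONTROL": {
        "emergency_visits": (0.19, 0.87),
        "outpatient_visits": (6.30, 0.57),
        "hospital_days": (0.05, 0.22),
        "surgical_hospital_days": (0.17, 0.87),
        "phone_calls": (2.04, 1.62),
        "teccu_contacts": (0.0, 0.0),
    },
    "NT": {
        "emergency_visits": (0.57, 1.17),
        "outpatient_visits": (4.25, 1.92),
        "hospital_days": (0.24, 0.77),
        "surgical_hospital_days": (0.26, 1.31),
        "phone_calls": (5.27, 1.35),
        "teccu_contacts": (0.0, 0.0),
    },
    "TECCU": {
        "emergency_visits": (0.27, 0.68),
        "outpatient_visits": (3.79, 1.38),
        "hospital_days": (0.11, 0.32),
        "surgical_hospital_days": (0.19, 0.89),
        "phone_calls": (0.51, 0.76),
        "teccu_contacts": (33.15, 5.78),
    },
}

#: Fraction of telephone contacts handled by a physician, implied by the
#: printed per-patient phone costs (mean cost / calls vs the two unit rates).
PHONE_PHYSICIAN_FRACTION = {"CONTROL": 0.11, "NT": 0.18, "TECCU": 0.46}

#: Fraction of telemonitoring contacts answered by a physician, implied by
#: 68.96 € / 33.15 contacts = 2.08 €/contact between the 1.68/3.04 rates.
TECCU_PHYSICIAN_FRACTION = 0.295

#: Printed per-patient mean (SD) costs by category, EUR.
COST_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "CONTROL": {
        "emergency": (36.18, 165.03),
        "outpatient": (252.13, 22.91),
        "hospitalization": (14.79, 67.65),
        "surgery_hospitalization": (65.10, 297.74),
        "phone_calls": (32.05, 21.41),
        "teccu_contacts": (0.0, 0.0),
        "equipment": (0.0, 0.0),
        "absenteeism": (384.22, 418.00),
        "presenteeism": (363.06, 549.48),
        "visit_absence": (309.98, 113.41),
        "call_absence": (5.39, 3.94),
        "leisure_teccu": (0.0, 0.0),
        "total_productivity": (678.0, 686.0),
        "total": (1066.0, 678.0),
    },
    "NT": {
        "emergency": (108.15, 220.18),
        "outpatient": (170.03, 76.68),
        "hospitalization": (73.83, 238.20),
        "surgery_hospitalization": (97.41, 446.49),
        "phone_calls": (85.03, 20.31),
        "teccu_contacts": (0.0, 0.0),
        "equipment": (0.0, 0.0),
        "absenteeism": (206.74, 194.61),
        "presenteeism": (177.09, 317.12),
        "visit_absence": (214.52, 91.72),
        "call_absence": (15.69, 4.59),
        "leisure_teccu": (0.0, 0.0),
        "total_productivity": (466.0, 397.0),
        "total": (992.0, 804.0),
    },
    "TECCU": {
        "emergency": (51.03, 115.06),
        "outpatient": (151.67, 58.72),
        "hospitalization": (32.63, 97.70),
        "surgery_hospitalization": (71.82, 312.89),
        "phone_calls": (9.18, 11.31),
        "teccu_contacts": (68.96, 12.07),
        "equipment": (23.94, 0.0),
        "absenteeism": (213.97, 300.51),
        "presenteeism": (168.42, 224.04),
        "visit_absence": (187.22, 62.30),
        "call_absence": (1.71, 2.24),
        "leisure_teccu": (25.37, 4.42),
        "total_productivity": (407.0, 339.0),
        "total": (807.0, 623.0),
    },
}

#: Remission counts out of 21 per arm.
REMISSION_COUNTS = {
    "CONTROL": {"w0": 12, "w24": 15},
    "NT": {"w0": 8, "w24": 14},
    "TECCU": {"w0": 10, "w24": 17},
}

#: Printed per-arm remission-increase proportions.
REMISSION_INCREASE = {"CONTROL": 0.14, "NT": 0.29, "TECCU": 0.33}

#: Mean (SD) weeks in remission over the 24-week horizon.
WEEKS_IN_REMISSION = {
    "CONTROL": (14.27, 8.13),
    "NT": (17.24, 8.38),
    "TECCU": (17.89, 7.03),
}

#: EQ-5D utility summaries: per-arm medians at weeks 0/24 and the week-24
#: mean (SD) plus mean (SD) improvement over 24 weeks.
EQ5D = {
    "CONTROL": {
        "median_w0": 0.816, "median_w24": 1.00,
        "mean_w24": (0.93, 0.15), "mean_improvement": (0.10, 0.19),
    },
    "NT": {
        "median_w0": 0.825, "median_w24": 1.00,
        "mean_w24": (0.89, 0.16), "mean_improvement": (0.08, 0.18),
    },
    "TECCU": {
        "median_w0": 0.825, "median_w24": 1.00,
        "mean_w24": (0.90, 0.19), "mean_improvement": (0.09, 0.28),
    },
}

#: Gained QALYs per patient from the median utility improvements x 0.5 years.
GAINED_QALYS = {"CONTROL": 0.092, "NT": 0.088, "TECCU": 0.088}

#: Mean-difference ICER worked arithmetic: (delta cost, delta effect, ICER).
MEAN_ICER_ARITHMETIC = {
    ("TECCU", "CONTROL"): (-211.0, 0.191, -1105.0),
    ("TECCU", "NT"): (-135.0, 0.048, -2812.0),
    ("NT", "CONTROL"): (-77.0, 0.143, -538.0),
}

#: Demographics: sex split, disease split, not-working fraction, age summaries.
DEMOGRAPHICS = {
    "CONTROL": {"n": 21, "female": 9, "cd": 14, "not_working": 8,
                "age_median": 39.31, "age_range": (22, 61)},
    "NT": {"n": 21, "female": 9, "cd": 13, "not_working": 7,
           "age_median": 40.91, "age_range": (24, 60)},
    "TECCU": {"n": 21, "female": 12, "cd": 13, "not_working": 5,
              "age_median": 41.32, "age_range": (19, 66)},
}

#: Fecal calprotectin medians (ug/g) at weeks 0 and 24 (covariate only).
CALPROTECTIN_MEDIANS = {
    "CONTROL": {"w0": 330.0, "w24": 230.0},
    "NT": {"w0": 526.0, "w24": 168.0},
    "TECCU": {"w0": 490.0, "w24": 126.0},
}

#: Three TECCU-arm patients did not adhere to the follow-up schedule.
NONADHERENT_TECCU = 3


def worked_example_fixture() -> dict[str, Any]:
    """Return the published group-level summaries as one nested mapping.

    Keys: ``unit_costs``, ``resource_units``, ``cost_means``,
    ``remission_counts``, ``remission_increase``, ``weeks_in_remission``,
    ``eq5d``, ``gained_qalys``, ``mean_icer_arithmetic``, ``demographics``,
    ``calprotectin``, ``eur_to_usd``.
    """
    return {
        "unit_costs": dict(UNIT_COSTS),
        "teccu_contact_cost": dict(TECCU_CONTACT_COST),
        "resource_units": {a: dict(v) for a, v in RESOURCE_UNITS.items()},
        "phone_physician_fraction": dict(PHONE_PHYSICIAN_FRACTION),
        "teccu_physician_fraction": TECCU_PHYSICIAN_FRACTION,
        "cost_means": {a: dict(v) for a, v in COST_MEANS.items()},
        "remission_counts": {a: dict(v) for a, v in REMISSION_COUNTS.items()},
        "remission_increase": dict(REMISSION_INCREASE),
        "weeks_in_remission": dict(WEEKS_IN_REMISSION),
        "eq5d": {a: dict(v) for a, v in EQ5D.items()},
        "gained_qalys": dict(GAINED_QALYS),
        "mean_icer_arithmetic": dict(MEAN_ICER_ARITHMETIC),
        "demographics": {a: dict(v) for a, v in DEMOGRAPHICS.items()},
        "calprotectin": {a: dict(v) for a, v in CALPROTECTIN_MEDIANS.items()},
        "nonadherent_teccu": NONADHERENT_TECCU,
        "eur_to_usd": EUR_TO_USD,
    }
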