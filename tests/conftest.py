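import numpy as np
import pytest

import trialcea as t
from trialcea.data import Arm, Disease, PatientRecord, ResourceUse, Sex, WPAIResponse


@pytest.fixture(scope="session")
def unit_costs():
    return t.default_unit_costs()


@pytest.fixture(scope="session")
def flat_wage_costs():
    """Unit costs with a flat 15 EUR/h wage for hand-computable examples."""
    return t.default_unit_costs(
        wage_table={"M": (15.0,) * 6, "F": (15.0,) * 6})


def make_patient(patient_id="P1", arm=Arm.CONTROL, disease=Disease.CD, age=40,
                 sex=Sex.M, employed=True, hbi=2.0, sccai=1.0, pmayo=1.0,
                 eq5d=(0.8, 0.9), wpai_kwargs=None, **resource_kwargs):
    """A fully observed patient with constant scores across visits."""
    wk = wpai_kwargs or dict(hours_missed=0.0, hours_worked=40.0,
                             work_impairment_pct=0.0, social_impairment_pct=0.0,
                             not_working=False)
    if not employed:
        wk = dict(hours_missed=0.0, hours_worked=0.0, work_impairment_pct=0.0,
                  social_impairment_pct=wk.get("social_impairment_pct", 0.0),
                  not_working=True)
    rec = PatientRecord(
        patient_id=patient_id, arm=arm, disease=disease, age_years=age, sex=sex,
        employed=employed,
        hbi={w: (hbi if disease == Disease.CD else None) for w in (0, 12, 24)},
        sccai={w: (sccai if disease == Disease.UC else None) for w in (0, 12, 24)},
        pmayo={w: (pmayo if disease == Disease.UC else None) for w in (0, 12, 24)},
        eq5d={0: eq5d[0], 24: eq5d[1]},
        wpai={w: WPAIResponse(**wk) for w in (0, 12, 24)},
        resources=ResourceUse(**resource_kwargs),
    )
    rec.validate()
    return rec


@pytest.fixture(scope="session")
def complete_trial():
    cfg = t.default_config(seed=11)
    cfg.missingness = t.MissingnessConfig(mechanism="NONE")
    return t.generate_trial(cfg, seed=11)


@pytest.fixture(scope="session")
def trial_with_missing():
    return t.generate_trial(t.default_config(seed=12), seed=12)


@pytest.fixture(scope="session")
def small_impset(complete_trial):
    """m=2 identical completed datasets (complete trial needs no imputation)."""
    return t.impute(complete_trial, m=2, seed=5)
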