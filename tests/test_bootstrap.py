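"""Bootstrap CEA engine: draw bookkeeping, ICERs, quadrants, CEAC."""

import math

import numpy as np
import pandas as pd
import pytest

import trialcea as t
from trialcea.bootstrap import (bootstrap_contrast, ceac, default_wtp_grid, icer,
                                quadrant_probabilities, summarize_icer)
from trialcea.data import TrialDataError


def draws_frame(dc, de):
    dc, de = np.asarray(dc, dtype=float), np.asarray(de, dtype=float)
    return pd.DataFrame({"delta_cost": dc, "delta_effect": de,
                         "imputation": 1, "replicate": np.arange(1, len(dc) + 1)})


def test_draw_count_is_m_times_B(small_impset, unit_costs):
    draws = bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=25, seed=0,
                               unit_costs=unit_costs)
    assert len(draws) == small_impset.m * 25
    assert set(draws["imputation"]) == {1, 2}
    with pytest.raises(TrialDataError):
        bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=0, seed=0,
                           unit_costs=unit_costs)


def test_identical_arms_center_at_origin(complete_trial, unit_costs):
    """Contrasting an arm against a relabelled copy of itself centres at (0,0)."""
    teccu = [r for r in complete_trial if r.arm == t.Arm.TECCU]
    clones = []
    for r in teccu:
        c = r.copy()
        c.arm = t.Arm.NT
        c.patient_id = "clone-" + r.patient_id
        c.resources.teccu_contacts_nurse = 0
        c.resources.teccu_contacts_physician = 0
        c.resources.teccu_months = 0.0
        # keep costs identical by mirroring the dropped telemonitoring use
        r2 = r.copy()
        r2.resources.teccu_contacts_nurse = 0
        r2.resources.teccu_contacts_physician = 0
        r2.resources.teccu_months = 0.0
        clones.append(c)
        clones.append(r2)
    impset = t.impute(clones, m=2, seed=0)
    draws = bootstrap_contrast(impset, "TECCU", "NT", B=400, seed=1,
                               unit_costs=unit_costs)
    scale = np.abs(draws["delta_cost"]).mean()
    assert abs(draws["delta_cost"].median()) < 0.25 * scale + 1e-9
    assert abs(draws["delta_effect"].median()) <= 0.05


def test_draw_means_match_clt_oracle(unit_costs):
    """Bootstrap mean increments sit within 3 SE of the population difference."""
    cfg = t.default_config(seed=21)
    cfg.n_per_arm = 300
    cfg.missingness = t.MissingnessConfig(mechanism="NONE")
    records = t.generate_trial(cfg, seed=21)
    impset = t.impute(records, m=2, seed=0)
    from trialcea.bootstrap import arm_arrays
    ga = [r for r in records if r.arm == t.Arm.TECCU]
    gb = [r for r in records if r.arm == t.Arm.CONTROL]
    aa, ab = arm_arrays(ga, unit_costs), arm_arrays(gb, unit_costs)
    true_dc = aa["total"].mean() - ab["total"].mean()
    se_dc = np.sqrt(aa["total"].var() / len(ga) + ab["total"].var() / len(gb))
    draws = bootstrap_contrast(impset, "TECCU", "CONTROL", B=300, seed=3,
                               unit_costs=unit_costs)
    # the bootstrap distribution centres on the sample mean difference
    assert abs(draws["delta_cost"].mean() - true_dc) < 4 * se_dc / np.sqrt(len(draws))
    true_de = aa["rem_change"].mean() - ab["rem_change"].mean()
    se_de = np.sqrt(aa["rem_change"].var() / len(ga) + ab["rem_change"].var() / len(gb))
    assert abs(draws["delta_effect"].mean() - true_de) < 3 * se_de


@pytest.mark.parametrize("dc,de,expected", [
    (-211.0, 0.191, -1104.7120419),
    (-135.0, 0.048, -2812.5),
    (-77.0, 0.143, -538.4615385),
])
def test_icer_ratio(dc, de, expected):
    assert icer(dc, de) == pytest.approx(expected)


def test_icer_undefined_at_zero_effect():
    assert math.isnan(icer(100.0, 0.0))


def test_summarize_icer_percentiles():
    d = draws_frame([-100.0] * 200, [0.2] * 200)
    med, (lo, hi) = summarize_icer(d)
    assert med == lo == hi == pytest.approx(-500.0)
    rng = np.random.default_rng(0)
    d2 = draws_frame(rng.normal(-100, 10, 1000), np.full(1000, 0.2))
    med2, (lo2, hi2) = summarize_icer(d2)
    assert lo2 < med2 < hi2
    with pytest.raises(TrialDataError, match="increase B"):
        summarize_icer(draws_frame([1.0] * 50, [1.0] * 50))


def test_quadrant_probabilities_sum_to_one_and_tie_rule():
    d = draws_frame([-1, -1, 1, 1, 0], [1, -1, 1, -1, 0])
    q = quadrant_probabilities(d)
    assert sum(q.values()) == 1.0
    assert q["dominant"] == 0.2
    # the boundary draw (0, 0) is never dominant
    assert q["dominated"] == pytest.approx(0.4)
    all_dom = quadrant_probabilities(draws_frame([-1] * 10, [1] * 10))
    assert all_dom["dominant"] == 1.0


def test_quadrants_quarter_under_centered_symmetric_draws():
    rng = np.random.default_rng(5)
    n = 40000
    d = draws_frame(rng.standard_normal(n), rng.standard_normal(n))
    q = quadrant_probabilities(d)
    for v in q.values():
        assert v == pytest.approx(0.25, abs=3 * 0.5 / np.sqrt(n))


def test_ceac_at_zero_is_probability_of_cost_saving():
    rng = np.random.default_rng(1)
    d = draws_frame(rng.normal(-50, 100, 2000), rng.normal(0.1, 0.2, 2000))
    curve = ceac(d, np.array([0.0, 1000.0]))
    assert curve.probability[0] == (d["delta_cost"] < 0).mean()


def test_ceac_monotone_when_all_effects_positive():
    rng = np.random.default_rng(2)
    d = draws_frame(rng.normal(0, 100, 2000), np.abs(rng.normal(0.2, 0.1, 2000)))
    curve = ceac(d, default_wtp_grid())
    assert np.all(np.diff(curve.probability) >= 0)


def test_ceac_rejects_negative_wtp():
    d = draws_frame([1.0], [1.0])
    with pytest.raises(TrialDataError):
        ceac(d, np.array([-5.0, 0.0]))


def test_bootstrap_determinism_and_stream_stability(small_impset, unit_costs):
    a = bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=30, seed=7,
                           unit_costs=unit_costs)
    b = bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=30, seed=7,
                           unit_costs=unit_costs)
    assert a.equals(b)
    # enlarging B extends the draw set without reshuffling earlier replicates
    bigger = bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=60, seed=7,
                                unit_costs=unit_costs)
    merged = bigger[bigger["replicate"] <= 30].reset_index(drop=True)
    assert merged.equals(a)
    c = bootstrap_contrast(small_impset, "TECCU", "CONTROL", B=30, seed=8,
                           unit_costs=unit_costs)
    assert not a.equals(c)
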