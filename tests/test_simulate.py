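"""Synthetic trial generator: structure, invariants, calibration."""

import numpy as np
import pytest
from scipy import stats

import trialcea as t
from trialcea.data import Arm, TrialDataError, patients_to_frame
from trialcea.simulate import (MissingnessConfig, default_config, expected_total_cost,
                               generate_trial, worked_example_fixture)


def test_default_trial_shape(trial_with_missing):
    assert len(trial_with_missing) == 63
    for arm in Arm:
        assert sum(r.arm == arm for r in trial_with_missing) == 21


def test_default_missingness_is_three_teccu_dropouts(trial_with_missing):
    dropped = [r for r in trial_with_missing if r.eq5d[24] is None]
    assert len(dropped) == 3
    assert all(r.arm == Arm.TECCU for r in dropped)
    for r in dropped:
        assert r.primary_score(24) is None
        assert r.wpai[24].social_impairment_pct is None
        assert r.eq5d[0] is not None  # baseline always observed


def test_no_missingness_option(complete_trial):
    for r in complete_trial:
        assert r.eq5d[24] is not None and r.primary_score(24) is not None


def test_mcar_mechanism_and_validation():
    cfg = default_config(seed=3)
    cfg.missingness = MissingnessConfig(mechanism="MCAR", rate=0.3, arm_dropouts={})
    recs = generate_trial(cfg, seed=3)
    frame = patients_to_frame(recs)
    assert frame["eq5d_w24"].isna().any()
    with pytest.raises(TrialDataError):
        MissingnessConfig(mechanism="WEIRD").validate()
    with pytest.raises(TrialDataError):
        MissingnessConfig(rate=1.5).validate()


def test_generated_records_satisfy_invariants(complete_trial):
    for r in complete_trial:
        r.validate()  # raises on any violated invariant
        for wk in (0, 12, 24):
            w = r.wpai[wk]
            if w.not_working:
                assert w.hours_worked == 0.0
            assert 0 <= w.social_impairment_pct <= 100
        if r.arm != Arm.TECCU:
            assert r.resources.teccu_months == 0.0
        else:
            assert r.resources.teccu_months == 6.0


def test_same_seed_identical_output():
    a = patients_to_frame(generate_trial(default_config(seed=5), seed=5))
    b = patients_to_frame(generate_trial(default_config(seed=5), seed=5))
    c = patients_to_frame(generate_trial(default_config(seed=6), seed=6))
    assert a.equals(b)
    assert not a.equals(c)


def test_remission_and_costs_are_negatively_linked(unit_costs):
    """Latent severity couples outcomes: week-24 remitters cost less."""
    cfg = default_config(seed=8)
    cfg.n_per_arm = 400
    cfg.missingness = MissingnessConfig(mechanism="NONE")
    recs = [r for r in generate_trial(cfg, seed=8) if r.arm == Arm.CONTROL]
    from trialcea.effects import record_remission
    totals = np.array([t.total_cost(r, unit_costs).total for r in recs])
    rem = np.array([record_remission(r, 24) for r in recs], dtype=bool)
    u = stats.mannwhitneyu(totals[rem], totals[~rem], alternative="less")
    assert u.pvalue < 0.01


@pytest.fixture(scope="module")
def large_trial():
    cfg = default_config(seed=13)
    cfg.n_per_arm = 3000
    cfg.missingness = MissingnessConfig(mechanism="NONE")
    return cfg, generate_trial(cfg, seed=13)


def test_arm_calibration_against_published_totals(unit_costs, large_trial):
    """Large-sample arm means reproduce the published mean total costs."""
    fixture = worked_example_fixture()
    cfg, recs = large_trial
    frame = t.cost_frame(recs, unit_costs)
    for arm in ("CONTROL", "NT", "TECCU"):
        target, sd = fixture["cost_means"][arm]["total"]
        got = frame.loc[frame["arm"] == arm, "total"]
        se = got.std() / np.sqrt(len(got))
        assert abs(got.mean() - target) < 3 * se + 0.02 * target
        # closed-form expectation matches the published target almost exactly
        assert expected_total_cost(cfg.arms[arm], arm, unit_costs) == pytest.approx(
            target, rel=1e-3)


def test_remission_proportions_match_published_counts(large_trial):
    _, recs = large_trial
    from trialcea.effects import record_remission
    fixture = worked_example_fixture()
    for arm in ("CONTROL", "NT", "TECCU"):
        sub = [r for r in recs if r.arm.value == arm]
        for wk, key in ((0, "w0"), (24, "w24")):
            p_target = fixture["remission_counts"][arm][key] / 21
            p_got = np.mean([record_remission(r, wk) for r in sub])
            assert p_got == pytest.approx(p_target, abs=3 * 0.5 / np.sqrt(len(sub)) + 0.01)


def test_fixture_contains_published_worked_values():
    f = worked_example_fixture()
    assert f["unit_costs"]["outpatient_visit"] == 40.02
    assert f["remission_counts"]["TECCU"]["w24"] == 17
    assert f["eq5d"]["CONTROL"]["median_w0"] == 0.816
    assert f["mean_icer_arithmetic"][("TECCU", "CONTROL")] == (-211.0, 0.191, -1105.0)


def test_invalid_config_rejected():
    cfg = default_config()
    cfg.n_per_arm = 0
    with pytest.raises(TrialDataError):
        generate_trial(cfg)
    cfg2 = default_config()
    del cfg2.arms["NT"]
    with pytest.raises(TrialDataError):
        cfg2.validate()
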