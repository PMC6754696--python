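"""Probabilistic cost-effectiveness engine.

For a pairwise arm contrast, the stratified nonparametric bootstrap resamples
n patients with replacement within each arm, in each of the m imputed
datasets, and records the incremental mean cost and incremental effect
(remission-increase difference or mean-QALY difference) of every resample.
The pooled m x B draws yield percentile ICER intervals, cost-effectiveness
plane quadrant probabilities and acceptability curves.

The acceptability criterion is net monetary benefit: an intervention is
cost-effective at willingness-to-pay lambda when lambda * dE - dC > 0.  The
ratio-threshold rule is sign-ambiguous when dE < 0; NMB is well defined
everywhere and reproduces the characteristic *decreasing* QALY acceptability
curves seen when a majority of draws carry negative incremental effects.

Random numbers are disciplined: each (imputation, replicate) pair gets its
own counter-derived substream of the master seed, so summaries are draw-order
independent and enlarging B never reshuffles earlier draws; sensitivity
scenarios reuse identical resample indices (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costs as costmod
from . import effects as effmod
from .data import Arm, TrialDataError, UnitCostTable
from .impute import ImputationSet, rubin_pool

DEFAULT_WTP_MAX = 20_000.0
DEFAULT_WTP_STEP = 500.0

EFFECT_MEASURES = ("remission", "qaly")


@dataclass
class IncrementalDraw:
    """One bootstrap draw of (incremental cost, incremental effect)."""

    delta_cost: float
    delta_effect: float
    imputation_index: int
    replicate_index: int


@dataclass
class CEACurve:
    """P(cost-effective) as a function of willingness to pay."""

    wtp_grid: np.ndarray
    probability: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probability})


@dataclass
class ContrastResult:
    """Bootstrap summaries for one ordered arm contrast and effect measure."""

    contrast: tuple[str, str]
    effect_measure: str
    draws: pd.DataFrame
    delta_cost: float
    delta_cost_variance: float
    delta_effect: float
    delta_effect_variance: float
    mean_icer: float
    median_icer: float
    icer_ci: tuple[float, float]
    quadrant_probs: dict[str, float]
    ceac: CEACurve
    label: str = "base"


def default_wtp_grid(wtp_max: float = DEFAULT_WTP_MAX,
                     wtp_step: float = DEFAULT_WTP_STEP) -> np.ndarray:
    """Willingness-to-pay grid from 0 to ``wtp_max`` inclusive."""
    n = int(round(wtp_max / wtp_step))
    return np.linspace(0.0, wtp_max, n + 1)


def resample_rng(seed: int, imputation: int, replicate: int) -> np.random.Generator:
    """Deterministic substream for one (imputation, replicate) pair."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF, spawn_key=(imputation, replicate)))


def arm_arrays(records, unit_costs: UnitCostTable,
               healthcare_multiplier: float = 1.0,
               indirect_multiplier: float = 1.0) -> dict[str, np.ndarray]:
    """Per-patient cost and effect vectors for one completed record list.

    The two multipliers rescale the health-care (incl. equipment) and the
    productivity/leisure blocks, for one-way sensitivity scenarios.
    """
    hc, prod, rem0, rem24, qalys = [], [], [], [], []
    for rec in records:
        b = costmod.total_cost(rec, unit_costs)
        e = effmod.effect_summary(rec)
        hc.append(b.total_healthcare)
        prod.append(b.total_productivity)
        rem0.append(e.in_remission_w0)
        rem24.append(e.in_remission_w24)
        qalys.append(e.qaly)
    hc = np.asarray(hc)
    prod = np.asarray(prod)
    return {
        "total": hc * healthcare_multiplier + prod * indirect_multiplier,
        "rem_change": np.asarray(rem24, dtype=float) - np.asarray(rem0, dtype=float),
        "qaly": np.asarray(qalys, dtype=float),
    }


def _effect_vector(arrs: dict[str, np.ndarray], measure: str) -> np.ndarray:
    if measure == "remission":
        return arrs["rem_change"]
    if measure == "qaly":
        return arrs["qaly"]
    raise TrialDataError(f"unknown effect measure {measure!r}; "
                         f"expected one of {EFFECT_MEASURES}")


def bootstrap_contrast(impset: ImputationSet, arm_a: Arm | str, arm_b: Arm | str,
                       B: int, seed: int, unit_costs: UnitCostTable,
                       effect_measure: str = "remission",
                       healthcare_multiplier: float = 1.0,
                       indirect_multiplier: float = 1.0) -> pd.DataFrame:
    """All m x B incremental (cost, effect) draws for an ordered contrast.

    Within each imputation, each replicate resamples n patients with
    replacement within each arm and takes differences of group summaries
    (arm A minus arm B).
    """
    if B < 1:
        raise TrialDataError(f"need B >= 1 bootstrap replicates, got {B}")
    arm_a, arm_b = Arm(arm_a), Arm(arm_b)
    rows = []
    for d, dataset in enumerate(impset.datasets, start=1):
        group_a = [r for r in dataset if r.arm == arm_a]
        group_b = [r for r in dataset if r.arm == arm_b]
        if len(group_a) < 2 or len(group_b) < 2:
            raise TrialDataError(
                f"contrast {arm_a.value} vs {arm_b.value}: both arms need n >= 2")
        arrs_a = arm_arrays(group_a, unit_costs, healthcare_multiplier, indirect_multiplier)
        arrs_b = arm_arrays(group_b, unit_costs, healthcare_multiplier, indirect_multiplier)
        eff_a, eff_b = _effect_vector(arrs_a, effect_measure), _effect_vector(arrs_b, effect_measure)
        na, nb = len(group_a), len(group_b)
        for b in range(1, B + 1):
            rng = resample_rng(seed, d, b)
            ia = rng.integers(0, na, size=na)
            ib = rng.integers(0, nb, size=nb)
            rows.append((
                arrs_a["total"][ia].mean() - arrs_b["total"][ib].mean(),
                eff_a[ia].mean() - eff_b[ib].mean(),
                d, b,
            ))
    return pd.DataFrame(rows, columns=["delta_cost", "delta_effect",
                                       "imputation", "replicate"])


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio; nan (undefined) when dE = 0."""
    if delta_effect == 0:
        return math.nan
    return delta_cost / delta_effect


def summarize_icer(draws: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Median and 2.5-97.5 percentile interval of the defined ICER draws."""
    de = draws["delta_effect"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    defined = de != 0
    if defined.sum() < 100:
        raise TrialDataError(
            f"only {int(defined.sum())} draws have a defined ICER; increase B")
    ratios = dc[defined] / de[defined]
    lo, med, hi = np.percentile(ratios, [2.5, 50.0, 97.5])
    return float(med), (float(lo), float(hi))


def quadrant_probabilities(draws: pd.DataFrame) -> dict[str, float]:
    """Empirical cost-effectiveness-plane quadrant shares.

    ``dominant`` is greater effect at lower cost (dE > 0, dC < 0).  Boundary
    draws are assigned deterministically to the unfavourable side (dE = 0
    counts as no gain, dC = 0 as not cheaper) so the four shares sum to 1
    exactly and a boundary draw is never counted dominant.
    """
    if len(draws) == 0:
        raise TrialDataError("quadrant_probabilities: no draws")
    de = draws["delta_effect"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    n = len(draws)
    gain, cheaper = de > 0, dc < 0
    return {
        "dominant": float((gain & cheaper).sum() / n),
        "more_effective_more_costly": float((gain & ~cheaper).sum() / n),
        "less_effective_less_costly": float((~gain & cheaper).sum() / n),
        "dominated": float((~gain & ~cheaper).sum() / n),
    }


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray | None = None) -> CEACurve:
    """Acceptability curve: share of draws with positive net monetary benefit.

    At lambda = 0 this is exactly P(dC < 0), the probability of being cost
    saving.  When some draws carry dE < 0 the curve need not be monotone and
    tends to P(dE > 0) as lambda grows.
    """
    if len(draws) == 0:
        raise TrialDataError("ceac: no draws")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if (grid < 0).any():
        raise TrialDataError("ceac: willingness-to-pay values must be >= 0")
    de = draws["delta_effect"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACurve(wtp_grid=grid, probability=prob)


def pooled_increments(impset: ImputationSet, draws: pd.DataFrame,
                      arm_a: Arm | str, arm_b: Arm | str,
                      unit_costs: UnitCostTable, effect_measure: str,
                      healthcare_multiplier: float = 1.0,
                      indirect_multiplier: float = 1.0,
                      ) -> tuple[float, float, float, float]:
    """Rubin-pooled point estimates of (dC, dE) with total variances.

    The per-imputation point estimate is the full-sample mean difference; its
    within-imputation variance is estimated from that imputation's bootstrap
    draws.
    """
    arm_a, arm_b = Arm(arm_a), Arm(arm_b)
    dc_est, de_est, dc_var, de_var = [], [], [], []
    for d, dataset in enumerate(impset.datasets, start=1):
        ga = [r for r in dataset if r.arm == arm_a]
        gb = [r for r in dataset if r.arm == arm_b]
        aa = arm_arrays(ga, unit_costs, healthcare_multiplier, indirect_multiplier)
        ab = arm_arrays(gb, unit_costs, healthcare_multiplier, indirect_multiplier)
        dc_est.append(aa["total"].mean() - ab["total"].mean())
        de_est.append(_effect_vector(aa, effect_measure).mean()
                      - _effect_vector(ab, effect_measure).mean())
        sub = draws[draws["imputation"] == d]
        dc_var.append(sub["delta_cost"].var(ddof=1))
        de_var.append(sub["delta_effect"].var(ddof=1))
    dc, dc_tot = rubin_pool(dc_est, dc_var)
    de, de_tot = rubin_pool(de_est, de_var)
    return dc, dc_tot, de, de_tot


def analyze_contrast(impset: ImputationSet, arm_a: Arm | str, arm_b: Arm | str,
                     unit_costs: UnitCostTable, effect_measure: str = "remission",
                     B: int = 1000, seed: int = 0,
                     wtp_grid: np.ndarray | None = None,
                     healthcare_multiplier: float = 1.0,
                     indirect_multiplier: float = 1.0,
                     label: str = "base") -> ContrastResult:
    """Full bootstrap CEA for one ordered contrast and one effect measure."""
    draws = bootstrap_contrast(impset, arm_a, arm_b, B=B, seed=seed,
                               unit_costs=unit_costs, effect_measure=effect_measure,
                               healthcare_multiplier=healthcare_multiplier,
                               indirect_multiplier=indirect_multiplier)
    dc, dc_var, de, de_var = pooled_increments(
        impset, draws, arm_a, arm_b, unit_costs, effect_measure,
        healthcare_multiplier, indirect_multiplier)
    median, ci = summarize_icer(draws)
    return ContrastResult(
        contrast=(Arm(arm_a).value, Arm(arm_b).value),
        effect_measure=effect_measure,
        draws=draws,
        delta_cost=dc, delta_cost_variance=dc_var,
        delta_effect=de, delta_effect_variance=de_var,
        mean_icer=icer(dc, de),
        median_icer=median, icer_ci=ci,
        quadrant_probs=quadrant_probabilities(draws),
        ceac=ceac(draws, wtp_grid),
        label=label,
    )
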