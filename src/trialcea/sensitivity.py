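"""One-way cost-driver sensitivity scenarios.

Each scenario rescales the health-care block (including equipment) and the
productivity/leisure block of every patient's cost breakdown by independent
multipliers (the trial varied both over +/-60%) and recomputes the bootstrap
summaries.  All scenarios share the resample indices of the base analysis
(common random numbers), so differences between scenario curves reflect the
cost scaling alone, not Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import bootstrap as bs
from .costs import CostBreakdown, HEALTHCARE_FIELDS, PRODUCTIVITY_FIELDS
from .data import TrialDataError, UnitCostTable
from .impute import ImputationSet


@dataclass(frozen=True)
class SensitivityScenario:
    """Multipliers for the two cost blocks; (1, 1) is the base case."""

    healthcare_multiplier: float = 1.0
    indirect_multiplier: float = 1.0
    label: str = "base"

    def validate(self) -> None:
        for name in ("healthcare_multiplier", "indirect_multiplier"):
            v = getattr(self, name)
            if not v > 0:
                raise TrialDataError(f"scenario {self.label!r}: {name} must be > 0, got {v}")


def default_scenarios(low: float = 0.4, high: float = 1.6) -> list[SensitivityScenario]:
    """The +/-60% one-at-a-time grid plus the base case and joint extremes."""
    out = [SensitivityScenario(1.0, 1.0, "base")]
    for m, tag in ((low, f"-{(1 - low):.0%}"), (high, f"+{(high - 1):.0%}")):
        out.append(SensitivityScenario(m, 1.0, f"healthcare{tag}"))
        out.append(SensitivityScenario(1.0, m, f"indirect{tag}"))
        out.append(SensitivityScenario(m, m, f"both{tag}"))
    return out


def apply_scenario(breakdowns: Iterable[CostBreakdown] | pd.DataFrame,
                   scenario: SensitivityScenario):
    """Rescale cost breakdowns by the scenario multipliers, totals recomputed.

    Accepts a list of :class:`CostBreakdown` or a cost DataFrame and returns
    the same shape back.
    """
    scenario.validate()
    mh, mp = scenario.healthcare_multiplier, scenario.indirect_multiplier
    hc_cols = list(HEALTHCARE_FIELDS) + ["equipment"]
    if isinstance(breakdowns, pd.DataFrame):
        out = breakdowns.copy()
        for c in hc_cols:
            out[c] = out[c] * mh
        for c in PRODUCTIVITY_FIELDS:
            out[c] = out[c] * mp
        out["total_healthcare"] = out[hc_cols].sum(axis=1)
        out["total_productivity"] = out[list(PRODUCTIVITY_FIELDS)].sum(axis=1)
        out["total"] = out["total_healthcare"] + out["total_productivity"]
        return out
    scaled = []
    for b in breakdowns:
        kwargs = {f: getattr(b, f) * mh for f in hc_cols}
        kwargs.update({f: getattr(b, f) * mp for f in PRODUCTIVITY_FIELDS})
        scaled.append(CostBreakdown(**kwargs).finalize())
    return scaled


def scenario_ceacs(impset: ImputationSet, arm_a, arm_b,
                   scenarios: Sequence[SensitivityScenario],
                   unit_costs: UnitCostTable, effect_measure: str = "remission",
                   B: int = 1000, seed: int = 0,
                   wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Acceptability curves per scenario, in long format.

    Returns columns ``scenario``, ``healthcare_multiplier``,
    ``indirect_multiplier``, ``wtp``, ``probability``.  Every scenario uses
    the same seed, hence identical resample indices.
    """
    frames = []
    for sc in scenarios:
        sc.validate()
        draws = bs.bootstrap_contrast(
            impset, arm_a, arm_b, B=B, seed=seed, unit_costs=unit_costs,
            effect_measure=effect_measure,
            healthcare_multiplier=sc.healthcare_multiplier,
            indirect_multiplier=sc.indirect_multiplier)
        curve = bs.ceac(draws, wtp_grid).as_frame()
        curve.insert(0, "scenario", sc.label)
        curve.insert(1, "healthcare_multiplier", sc.healthcare_multiplier)
        curve.insert(2, "indirect_multiplier", sc.indirect_multiplier)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)
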