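"""Model/Results interface tying the pipeline together.

:class:`CostEffectivenessModel` is built from patient-level trial records and
a unit-cost table; :meth:`~CostEffectivenessModel.fit` runs multiple
imputation, the stratified bootstrap for the three pairwise contrasts and
both effect measures, and returns a :class:`CEAResults` carrying incremental
costs/effects with Rubin-pooled variances, ICER summaries, plane quadrant
probabilities and acceptability curves, with ``summary()``, plotting,
sensitivity scenarios and CSV export hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bootstrap as bs
from . import costs as costmod
from . import effects as effmod
from . import sensitivity as sens
from . import simulate as sim
from .data import (Arm, PatientRecord, TrialDataError, UnitCostTable,
                   default_unit_costs, patients_to_frame, read_patients,
                   read_unit_costs, row_to_record, write_results)
from .impute import ImputationSet, impute

#: the three published pairwise contrasts, intervention first
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("TECCU", "CONTROL"), ("TECCU", "NT"), ("NT", "CONTROL"))


class CostEffectivenessModel:
    """Trial-based societal cost-effectiveness / cost-utility model.

    Parameters
    ----------
    patients : sequence of PatientRecord
        Patient-level data; week-12/24 outcomes may be missing.
    unit_costs : UnitCostTable, optional
        Price weights; defaults to the packaged published table.
    """

    def __init__(self, patients: Sequence[PatientRecord],
                 unit_costs: UnitCostTable | None = None):
        self.patients = list(patients)
        if not self.patients:
            raise TrialDataError("no patient records supplied")
        for p in self.patients:
            p.validate()
        self.unit_costs = unit_costs or default_unit_costs()
        self.unit_costs.validate()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, patients_path, unit_costs_path=None) -> "CostEffectivenessModel":
        costs = read_unit_costs(unit_costs_path) if unit_costs_path else None
        return cls(read_patients(patients_path), unit_costs=costs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       unit_costs: UnitCostTable | None = None) -> "CostEffectivenessModel":
        records = [row_to_record(row, rownum=i + 2)
                   for i, row in enumerate(df.to_dict("records"))]
        return cls(records, unit_costs=unit_costs)

    @classmethod
    def simulate(cls, config: sim.GeneratorConfig | None = None, seed: int = 0,
                 unit_costs: UnitCostTable | None = None) -> "CostEffectivenessModel":
        """Build the model on a synthetic trial calibrated to the published arms."""
        uc = unit_costs or default_unit_costs()
        cfg = config or sim.default_config(unit_costs=uc, seed=seed)
        return cls(sim.generate_trial(cfg, seed=seed), unit_costs=uc)

    # -- fitting ------------------------------------------------------------

    def fit(self, m: int = 5, B: int = 1000, seed: int = 0,
            wtp_max: float = bs.DEFAULT_WTP_MAX, wtp_step: float = bs.DEFAULT_WTP_STEP,
            effect_measures: Sequence[str] = bs.EFFECT_MEASURES,
            contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS) -> "CEAResults":
        """Impute, bootstrap every contrast x effect measure, and summarise."""
        impset = impute(self.patients, m=m, seed=seed)
        grid = bs.default_wtp_grid(wtp_max, wtp_step)
        results: dict[tuple[str, str, str], bs.ContrastResult] = {}
        for arm_a, arm_b in contrasts:
            for measure in effect_measures:
                results[(arm_a, arm_b, measure)] = bs.analyze_contrast(
                    impset, arm_a, arm_b, unit_costs=self.unit_costs,
                    effect_measure=measure, B=B, seed=seed, wtp_grid=grid)
        return CEAResults(model=self, impset=impset, contrasts=results,
                          m=m, B=B, seed=seed, wtp_grid=grid)


@dataclass
class CEAResults:
    """Fitted cost-effectiveness results for all contrasts and effect measures."""

    model: CostEffectivenessModel
    impset: ImputationSet
    contrasts: dict[tuple[str, str, str], bs.ContrastResult]
    m: int
    B: int
    seed: int
    wtp_grid: np.ndarray
    _cost_table: pd.DataFrame | None = field(default=None, repr=False)

    # -- per-arm descriptives (averaged over imputations) --------------------

    def cost_table(self) -> pd.DataFrame:
        """Mean per-patient cost by arm and category, averaged over imputations."""
        if self._cost_table is None:
            frames = []
            for d, dataset in enumerate(self.impset.datasets, start=1):
                f = costmod.cost_frame(dataset, self.model.unit_costs)
                f["imputation"] = d
                frames.append(f)
            allf = pd.concat(frames, ignore_index=True)
            num = allf.drop(columns=["patient_id", "imputation"])
            self._cost_table = num.groupby("arm").mean().reset_index()
        return self._cost_table

    def effect_table(self) -> pd.DataFrame:
        """Arm-level effect summaries averaged over imputations."""
        frames = []
        for dataset in self.impset.datasets:
            f = effmod.effect_frame(dataset)
            frames.append(f)
        allf = pd.concat(frames, ignore_index=True)
        g = allf.groupby("arm")
        out = pd.DataFrame({
            "remission_w0": g["in_remission_w0"].mean(),
            "remission_w24": g["in_remission_w24"].mean(),
            "remission_increase": (g["in_remission_w24"].mean()
                                   - g["in_remission_w0"].mean()),
            "weeks_in_remission": g["weeks_in_remission"].mean(),
            "qaly_gained": g["qaly"].mean(),
            "eq5d_w24_mean": g["eq5d_w24"].mean(),
        })
        return out.reset_index()

    # -- contrast summaries --------------------------------------------------

    def contrast_table(self) -> pd.DataFrame:
        rows = []
        usd = self.model.unit_costs.eur_to_usd
        for (a, b, measure), r in self.contrasts.items():
            ceac0 = float(r.ceac.probability[0])
            ceac_max = float(r.ceac.probability[-1])
            rows.append({
                "contrast": f"{a} vs {b}", "effect_measure": measure,
                "delta_cost_eur": r.delta_cost,
                "delta_cost_se": np.sqrt(r.delta_cost_variance),
                "delta_effect": r.delta_effect,
                "delta_effect_se": np.sqrt(r.delta_effect_variance),
                "mean_icer_eur": r.mean_icer,
                "mean_icer_usd": r.mean_icer * usd,
                "median_icer_eur": r.median_icer,
                "icer_ci_low": r.icer_ci[0], "icer_ci_high": r.icer_ci[1],
                "p_dominant": r.quadrant_probs["dominant"],
                "p_cost_saving": ceac0,
                "p_cost_effective_wtp_max": ceac_max,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        lines = []
        lines.append("Trial-based societal cost-effectiveness analysis")
        lines.append(f"  patients: {len(self.model.patients)}   imputations (m): {self.m}"
                     f"   bootstrap replicates per imputation (B): {self.B}"
                     f"   seed: {self.seed}")
        lines.append(f"  willingness-to-pay grid: 0 .. {self.wtp_grid[-1]:,.0f} EUR")
        lines.append("")
        ct = self.cost_table().set_index("arm")
        lines.append("Mean societal cost per patient (EUR, pooled over imputations)")
        for arm in ct.index:
            lines.append(f"  {arm:8s} health care {ct.loc[arm, 'total_healthcare']:9.2f}"
                         f"   productivity {ct.loc[arm, 'total_productivity']:9.2f}"
                         f"   total {ct.loc[arm, 'total']:9.2f}")
        lines.append("")
        et = self.effect_table().set_index("arm")
        lines.append("Effects (pooled over imputations)")
        for arm in et.index:
            lines.append(
                f"  {arm:8s} remission {et.loc[arm, 'remission_w0']:.2f} -> "
                f"{et.loc[arm, 'remission_w24']:.2f}"
                f" (increase {et.loc[arm, 'remission_increase']:+.2f})"
                f"   QALY gain {et.loc[arm, 'qaly_gained']:+.3f}")
        lines.append("")
        lines.append("Pairwise contrasts (arm A minus arm B)")
        hdr = (f"  {'contrast':18s} {'measure':9s} {'dC (EUR)':>10s} {'dE':>8s}"
               f" {'mean ICER':>10s} {'median ICER':>12s} {'95% CI':>22s}"
               f" {'P(dom)':>7s} {'P(CE@0)':>8s}")
        lines.append(hdr)
        for (a, b, measure), r in self.contrasts.items():
            ci = f"[{r.icer_ci[0]:,.0f}, {r.icer_ci[1]:,.0f}]"
            lines.append(
                f"  {a + ' vs ' + b:18s} {measure:9s} {r.delta_cost:10.1f}"
                f" {r.delta_effect:8.3f} {r.mean_icer:10.1f} {r.median_icer:12.1f}"
                f" {ci:>22s} {r.quadrant_probs['dominant']:7.3f}"
                f" {r.ceac.probability[0]:8.3f}")
        return "\n".join(lines)

    # -- sensitivity ---------------------------------------------------------

    def sensitivity(self, scenarios: Sequence[sens.SensitivityScenario] | None = None,
                    contrast: tuple[str, str] = ("TECCU", "CONTROL"),
                    effect_measure: str = "remission") -> pd.DataFrame:
        """Scenario acceptability curves with common random numbers."""
        scen = list(scenarios) if scenarios is not None else sens.default_scenarios()
        return sens.scenario_ceacs(
            self.impset, contrast[0], contrast[1], scen,
            unit_costs=self.model.unit_costs, effect_measure=effect_measure,
            B=self.B, seed=self.seed, wtp_grid=self.wtp_grid)

    # -- plotting ------------------------------------------------------------

    def plot_plane(self, contrast: tuple[str, str] = ("TECCU", "CONTROL"),
                   effect_measure: str = "remission", ax=None):
        """Scatter the bootstrap draws on the cost-effectiveness plane."""
        import matplotlib.pyplot as plt

        r = self.contrasts[(contrast[0], contrast[1], effect_measure)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(r.draws["delta_effect"], r.draws["delta_cost"], s=4, alpha=0.3)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        unit = "remission proportion" if effect_measure == "remission" else "QALYs"
        ax.set_xlabel(f"Incremental effect ({unit})")
        ax.set_ylabel("Incremental cost (EUR)")
        ax.set_title(f"{contrast[0]} vs {contrast[1]} "
                     f"(dominant {r.quadrant_probs['dominant']:.1%})")
        return ax

    def plot_ceac(self, contrast: tuple[str, str] = ("TECCU", "CONTROL"),
                  effect_measure: str = "remission", ax=None):
        """Plot the cost-effectiveness acceptability curve."""
        import matplotlib.pyplot as plt

        r = self.contrasts[(contrast[0], contrast[1], effect_measure)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(r.ceac.wtp_grid, r.ceac.probability)
        ax.set_ylim(0, 1)
        ax.set_xlabel("Willingness to pay (EUR per unit of effect)")
        ax.set_ylabel("P(cost-effective)")
        ax.set_title(f"{contrast[0]} vs {contrast[1]} ({effect_measure})")
        return ax

    # -- export --------------------------------------------------------------

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "patients": patients_to_frame(self.model.patients),
            "costs_per_arm": self.cost_table(),
            "effects_per_arm": self.effect_table(),
            "contrast_summary": self.contrast_table(),
        }
        for (a, b, measure), r in self.contrasts.items():
            tag = f"{a.lower()}_vs_{b.lower()}_{measure}"
            out[f"draws_{tag}"] = r.draws
            out[f"ceac_{tag}"] = r.ceac.as_frame()
        return out

    def save(self, out_dir: str | Path) -> dict:
        """Write all tables plus run metadata; returns the file manifest."""
        meta = {
            "seed": self.seed, "m": self.m, "B": self.B,
            "wtp_max": float(self.wtp_grid[-1]),
            "n_patients": len(self.model.patients),
            "unit_costs": self.model.unit_costs.to_dict(),
            "imputation_method": self.impset.method_tag,
        }
        return write_results(self.tables(), out_dir, metadata=meta)
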