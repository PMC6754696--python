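"""Effect measures: clinical remission and QALYs.

Remission is index-based: Harvey-Bradshaw index <= 4 for Crohn disease;
SCCAI <= 2 and partial Mayo <= 2 for ulcerative colitis (both are required
when both are recorded; if only one is recorded it decides).  The primary
effect is the within-arm increase in the proportion of patients in remission
between baseline and week 24.

QALYs follow the trial's gained-QALY convention: the improvement in the EQ-5D
utility index between baseline and week 24, multiplied by the 0.5-year
horizon.  An area-under-the-curve alternative (mean of the two utilities x
horizon) is available for sensitivity use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data import Disease, PatientRecord, TrialDataError

#: Remission thresholds per clinical index.
HBI_REMISSION_MAX = 4.0
SCCAI_REMISSION_MAX = 2.0
PMAYO_REMISSION_MAX = 2.0

#: Trial horizon in years (24 weeks = 6 months).
HORIZON_YEARS = 0.5


@dataclass
class EffectSummary:
    """Per-patient effect measures over the trial horizon."""

    patient_id: str
    arm: str
    in_remission_w0: bool
    in_remission_w24: bool
    weeks_in_remission: float
    qaly: float
    eq5d_w0: float
    eq5d_w24: float


def classify_remission(disease: Disease | str, score: float | None = None, *,
                       sccai: float | None = None,
                       pmayo: float | None = None) -> bool | None:
    """Remission status from clinical activity scores.

    For CD pass ``score`` (HBI).  For UC pass ``sccai`` and/or ``pmayo``
    (``score`` is accepted as an alias for ``sccai``); when both are present
    both must be at or below their thresholds.  Returns ``None`` when every
    relevant score is missing (to be imputed).
    """
    disease = Disease(disease)
    if disease == Disease.CD:
        if score is None:
            return None
        if score < 0:
            raise TrialDataError(f"HBI score must be >= 0, got {score}")
        return score <= HBI_REMISSION_MAX
    if sccai is None:
        sccai = score
    parts = []
    if sccai is not None:
        if sccai < 0:
            raise TrialDataError(f"SCCAI score must be >= 0, got {sccai}")
        parts.append(sccai <= SCCAI_REMISSION_MAX)
    if pmayo is not None:
        if pmayo < 0:
            raise TrialDataError(f"partial Mayo score must be >= 0, got {pmayo}")
        parts.append(pmayo <= PMAYO_REMISSION_MAX)
    if not parts:
        return None
    return all(parts)


def record_remission(rec: PatientRecord, week: int) -> bool | None:
    """Remission status of one patient at one visit, or ``None`` if unscored."""
    if rec.disease == Disease.CD:
        return classify_remission(Disease.CD, rec.hbi[week])
    return classify_remission(Disease.UC, sccai=rec.sccai[week], pmayo=rec.pmayo[week])


def qaly(eq5d_w0: float | None, eq5d_w24: float | None,
         horizon_years: float = HORIZON_YEARS, *, auc: bool = False) -> float | None:
    """QALYs over the horizon from the two utility assessments.

    Default is the gained-QALY convention: (U_24 - U_0) x horizon.  With
    ``auc=True`` the area under the (linearly interpolated) utility curve,
    ((U_0 + U_24)/2) x horizon, is returned instead.
    """
    if not horizon_years > 0:
        raise TrialDataError(f"horizon_years must be > 0, got {horizon_years}")
    if eq5d_w0 is None or eq5d_w24 is None:
        return None
    for u in (eq5d_w0, eq5d_w24):
        if not -1 <= u <= 1:
            raise TrialDataError(f"EQ-5D utility must be in [-1, 1], got {u}")
    if auc:
        return (eq5d_w0 + eq5d_w24) / 2.0 * horizon_years
    return (eq5d_w24 - eq5d_w0) * horizon_years


def weeks_in_remission(rec: PatientRecord) -> float:
    """Weeks spent in remission, by piecewise-constant expansion of visit status.

    The week-12 status covers weeks 1-12 and the week-24 status weeks 13-24;
    all three visits in remission gives the full 24 weeks.
    """
    total = 0.0
    for week, span in ((12, 12.0), (24, 12.0)):
        status = record_remission(rec, week)
        if status is None:
            return math.nan
        total += span if status else 0.0
    return total


def effect_summary(rec: PatientRecord) -> EffectSummary:
    """Per-patient effect measures; raises if outcomes are still missing."""
    r0, r24 = record_remission(rec, 0), record_remission(rec, 24)
    q = qaly(rec.eq5d[0], rec.eq5d[24])
    wir = weeks_in_remission(rec)
    if r0 is None or r24 is None or q is None or math.isnan(wir):
        raise TrialDataError(
            f"patient {rec.patient_id}: missing effect data; run imputation first")
    return EffectSummary(
        patient_id=rec.patient_id, arm=rec.arm.value,
        in_remission_w0=r0, in_remission_w24=r24,
        weeks_in_remission=wir, qaly=q,
        eq5d_w0=rec.eq5d[0], eq5d_w24=rec.eq5d[24],
    )


def remission_increase(group: Sequence[EffectSummary]) -> float:
    """Within-group change in the remission proportion between weeks 0 and 24."""
    if len(group) == 0:
        raise TrialDataError("remission_increase: empty group")
    n = len(group)
    return (sum(e.in_remission_w24 for e in group)
            - sum(e.in_remission_w0 for e in group)) / n


def qaly_mean(group: Sequence[EffectSummary]) -> float:
    if len(group) == 0:
        raise TrialDataError("qaly_mean: empty group")
    return sum(e.qaly for e in group) / len(group)


def incremental_effect(group_a: Sequence[EffectSummary], group_b: Sequence[EffectSummary],
                       measure: str = "remission_increase") -> float:
    """Difference in a group-level effect measure, A minus B."""
    fn = {"remission_increase": remission_increase, "qaly_mean": qaly_mean}.get(measure)
    if fn is None:
        raise TrialDataError(f"unknown effect measure {measure!r}")
    return fn(group_a) - fn(group_b)


def effect_frame(records: Iterable[PatientRecord]):
    """EffectSummary rows for a record collection as a DataFrame."""
    import pandas as pd

    return pd.DataFrame([effect_summary(r).__dict__ for r in records])
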