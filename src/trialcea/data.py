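"""Domain types, validation and delimited-text I/O for patient-level trial data.

One row per patient; repeated measures carry ``_w0/_w12/_w24`` suffixes and
missing values are empty cells.  Missingness is preserved (``None``), never
silently coerced to zero: week-24 outcomes of dropouts stay missing until the
multiple-imputation stage fills them in.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import published

WEEKS = (0, 12, 24)
TRIAL_WEEKS = 24
TRIAL_MONTHS = 6

#: Age bands of the wage table: closed lower bound, open upper bound.
WAGE_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (18, 25), (25, 35), (35, 45), (45, 55), (55, 65), (65, 120),
)


class TrialDataError(ValueError):
    """Raised for malformed or invalid trial data, naming the offending location."""


class Arm(str, enum.Enum):
    CONTROL = "CONTROL"
    NT = "NT"
    TECCU = "TECCU"


class Disease(str, enum.Enum):
    CD = "CD"  # Crohn disease (Harvey-Bradshaw index)
    UC = "UC"  # ulcerative colitis (SCCAI + partial Mayo)


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise TrialDataError(msg)


@dataclass
class WPAIResponse:
    """One 7-day-recall WPAI assessment.

    ``hours_missed`` (Q2) and ``hours_worked`` (Q4) are weekly hours;
    ``work_impairment_pct`` (Q5) and ``social_impairment_pct`` (Q6) are 0-100
    percentages.  Any field may be ``None`` (missing, to be imputed).
    """

    hours_missed: float | None = None
    hours_worked: float | None = None
    work_impairment_pct: float | None = None
    social_impairment_pct: float | None = None
    not_working: bool = False

    def validate(self, where: str = "wpai") -> None:
        for name in ("hours_missed", "hours_worked"):
            v = getattr(self, name)
            _check(v is None or v >= 0, f"{where}.{name}: hours must be >= 0, got {v}")
        for name in ("work_impairment_pct", "social_impairment_pct"):
            v = getattr(self, name)
            _check(v is None or 0 <= v <= 100,
                   f"{where}.{name}: percentage must be in [0, 100], got {v}")
        if self.not_working:
            _check(not self.hours_worked,
                   f"{where}: not_working patients must have hours_worked = 0")

    @property
    def is_complete(self) -> bool:
        if self.not_working:
            return self.social_impairment_pct is not None
        return all(getattr(self, f) is not None for f in
                   ("hours_missed", "hours_worked", "work_impairment_pct",
                    "social_impairment_pct"))


#: Integer count fields of ResourceUse (teccu_months is fractional).
RESOURCE_COUNT_FIELDS = (
    "emergency_visits", "outpatient_visits", "hospital_days",
    "surgical_hospital_days", "phone_contacts_nurse", "phone_contacts_physician",
    "teccu_contacts_nurse", "teccu_contacts_physician",
)


@dataclass
class ResourceUse:
    """Resource consumption over the 24-week horizon (hospital-registry counts).

    Counts may be ``None`` (missing, imputable); blank CSV cells stay missing
    rather than becoming zeros.
    """

    emergency_visits: int | None = 0
    outpatient_visits: int | None = 0
    hospital_days: int | None = 0
    surgical_hospital_days: int | None = 0
    phone_contacts_nurse: int | None = 0
    phone_contacts_physician: int | None = 0
    teccu_contacts_nurse: int | None = 0
    teccu_contacts_physician: int | None = 0
    teccu_months: float = 0.0

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, f) is not None for f in RESOURCE_COUNT_FIELDS)

    def validate(self, arm: Arm | None = None, where: str = "resources") -> None:
        for name in RESOURCE_COUNT_FIELDS:
            v = getattr(self, name)
            _check(v is None or (v == int(v) and v >= 0),
                   f"{where}.{name}: count must be a non-negative integer, got {v}")
        _check(0 <= self.teccu_months <= TRIAL_MONTHS,
               f"{where}.teccu_months: must be in [0, {TRIAL_MONTHS}], got {self.teccu_months}")
        if arm is not None and arm != Arm.TECCU:
            _check(not self.teccu_contacts_nurse and not self.teccu_contacts_physician
                   and not self.teccu_months,
                   f"{where}: telemonitoring fields must be 0 outside the TECCU arm")


@dataclass
class PatientRecord:
    """One participant: arm, disease, demographics, clinical scores, EQ-5D,
    WPAI responses and resource use.  Week-12/24 outcomes may be missing."""

    patient_id: str
    arm: Arm
    disease: Disease
    age_years: int
    sex: Sex
    employed: bool
    hbi: dict[int, float | None] = field(default_factory=lambda: dict.fromkeys(WEEKS))
    sccai: dict[int, float | None] = field(default_factory=lambda: dict.fromkeys(WEEKS))
    pmayo: dict[int, float | None] = field(default_factory=lambda: dict.fromkeys(WEEKS))
    eq5d: dict[int, float | None] = field(default_factory=lambda: {0: None, 24: None})
    wpai: dict[int, WPAIResponse] = field(
        default_factory=lambda: {w: WPAIResponse() for w in WEEKS})
    resources: ResourceUse = field(default_factory=ResourceUse)
    calprotectin: dict[int, float | None] = field(default_factory=lambda: {0: None, 24: None})

    def validate(self) -> None:
        where = f"patient {self.patient_id}"
        _check(self.age_years >= 18, f"{where}: age_years must be >= 18, got {self.age_years}")
        for wk, u in self.eq5d.items():
            _check(u is None or -1 <= u <= 1,
                   f"{where}: eq5d_w{wk} must be in [-1, 1], got {u}")
        for scores, name in ((self.hbi, "hbi"), (self.sccai, "sccai"), (self.pmayo, "pmayo")):
            for wk, s in scores.items():
                _check(s is None or s >= 0, f"{where}: {name}_w{wk} must be >= 0, got {s}")
        for wk, w in self.wpai.items():
            w.validate(where=f"{where} wpai_w{wk}")
            if self.employed is False:
                _check(w.not_working, f"{where}: unemployed patient must have not_working set")
        self.resources.validate(arm=self.arm, where=f"{where} resources")

    def primary_score(self, week: int) -> float | None:
        """Disease-specific activity index: HBI for CD, SCCAI for UC."""
        return self.hbi[week] if self.disease == Disease.CD else self.sccai[week]

    def copy(self) -> "PatientRecord":
        return dataclasses.replace(
            self,
            hbi=dict(self.hbi), sccai=dict(self.sccai), pmayo=dict(self.pmayo),
            eq5d=dict(self.eq5d),
            wpai={w: dataclasses.replace(r) for w, r in self.wpai.items()},
            resources=dataclasses.replace(self.resources),
            calprotectin=dict(self.calprotectin),
        )


# ---------------------------------------------------------------------------
# Unit costs


@dataclass
class UnitCostTable:
    """Price weights per resource unit (EUR) plus costing conventions.

    The default table reproduces the trial's published unit costs; the wage
    table is a sex x 10-year-age-band grid bounded by ``wage_min``/``wage_max``
    (the national statistics source values are not public, so it is plain
    config).  ``inflation_multiplier`` rescales all costs (price-index
    correction factors are likewise not public; default 1).
    """

    emergency_visit: float
    outpatient_visit: float
    hospital_day: float
    surgical_hospital_day: float
    phone_call_nurse: float
    phone_call_physician: float
    contact_minutes: float
    nurse_salary_per_min: float
    physician_salary_per_min: float
    teccu_rental_per_patient_month: float
    leisure_hour: float
    visit_absence_hours: float
    wage_min: float
    wage_max: float
    wage_table: dict[str, tuple[float, ...]]
    patient_phone_minutes: float = 10.0
    teccu_patient_minutes: float = 5.0
    leisure_hours_weekly: float = 0.0
    inflation_multiplier: float = 1.0
    eur_to_usd: float = published.EUR_TO_USD

    _POSITIVE = (
        "emergency_visit", "outpatient_visit", "hospital_day", "surgical_hospital_day",
        "phone_call_nurse", "phone_call_physician", "contact_minutes",
        "nurse_salary_per_min", "physician_salary_per_min",
        "teccu_rental_per_patient_month", "leisure_hour", "visit_absence_hours",
        "wage_min", "wage_max", "patient_phone_minutes", "teccu_patient_minutes",
        "inflation_multiplier", "eur_to_usd",
    )

    def validate(self) -> None:
        for name in self._POSITIVE:
            v = getattr(self, name)
            _check(v is not None and v > 0, f"unit_costs.{name}: must be > 0, got {v}")
        _check(self.leisure_hours_weekly >= 0,
               f"unit_costs.leisure_hours_weekly: must be >= 0, got {self.leisure_hours_weekly}")
        _check(self.wage_min <= self.wage_max, "unit_costs: wage_min must be <= wage_max")
        for sex in ("M", "F"):
            rates = self.wage_table.get(sex)
            _check(rates is not None and len(rates) == len(WAGE_AGE_BANDS),
                   f"unit_costs.wage_table.{sex}: need {len(WAGE_AGE_BANDS)} age-band rates")
            for r in rates:
                _check(self.wage_min <= r <= self.wage_max,
                       f"unit_costs.wage_table.{sex}: rate {r} outside "
                       f"[{self.wage_min}, {self.wage_max}]")

    def wage_for(self, sex: Sex | str, age_years: float) -> float:
        """Hourly wage (EUR) for a sex / age combination (human-capital valuation)."""
        rates = self.wage_table[Sex(sex).value]
        for (lo, hi), rate in zip(WAGE_AGE_BANDS, rates):
            if lo <= age_years < hi:
                return rate
        return rates[-1] if age_years >= WAGE_AGE_BANDS[-1][0] else rates[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wage_table"] = {s: list(v) for s, v in self.wage_table.items()}
        return d


#: Default wage grid (EUR/hour), within the published 12.04-25.23 bounds.
DEFAULT_WAGE_TABLE: dict[str, tuple[float, ...]] = {
    "M": (12.90, 14.20, 15.60, 17.10, 18.40, 15.80),
    "F": (12.04, 12.90, 13.90, 14.90, 15.80, 14.10),
}


def default_unit_costs(**overrides) -> UnitCostTable:
    """The packaged unit-cost table (published trial rates), with overrides."""
    u = published.UNIT_COSTS
    kwargs = dict(
        emergency_visit=u["emergency_visit"],
        outpatient_visit=u["outpatient_visit"],
        hospital_day=u["hospital_day"],
        surgical_hospital_day=u["surgical_hospital_day"],
        phone_call_nurse=u["phone_call_nurse"],
        phone_call_physician=u["phone_call_physician"],
        contact_minutes=u["contact_minutes"],
        nurse_salary_per_min=u["nurse_salary_per_min"],
        physician_salary_per_min=u["physician_salary_per_min"],
        teccu_rental_per_patient_month=u["teccu_rental_per_patient_month"],
        leisure_hour=u["leisure_hour"],
        visit_absence_hours=u["visit_absence_hours"],
        wage_min=u["wage_min"],
        wage_max=u["wage_max"],
        wage_table={s: tuple(v) for s, v in DEFAULT_WAGE_TABLE.items()},
    )
    kwargs.update(overrides)
    table = UnitCostTable(**kwargs)
    table.validate()
    return table


def read_unit_costs(path: str | Path) -> UnitCostTable:
    """Read a unit-cost YAML config; absent keys fall back to packaged defaults."""
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"unit-cost file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise TrialDataError(f"{path}: unit-cost config must be a mapping")
    known = {f.name for f in dataclasses.fields(UnitCostTable)}
    unknown = set(raw) - known
    if unknown:
        raise TrialDataError(f"{path}: unknown unit-cost keys {sorted(unknown)}")
    overrides = dict(raw)
    if "wage_table" in overrides:
        wt = overrides["wage_table"]
        if not isinstance(wt, Mapping):
            raise TrialDataError(f"{path}: wage_table must map sex to rate lists")
        overrides["wage_table"] = {s: tuple(v) for s, v in wt.items()}
    try:
        return default_unit_costs(**overrides)
    except TrialDataError as exc:
        raise TrialDataError(f"{path}: {exc}") from None


def write_unit_costs(table: UnitCostTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(table.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Patient CSV schema

SCHEMA_VERSION = "1"

_SCALAR_COLUMNS = ["patient_id", "arm", "disease", "age_years", "sex", "employed"]
_SCORE_COLUMNS = [f"{idx}_w{w}" for idx in ("hbi", "sccai", "pmayo") for w in WEEKS]
_EQ5D_COLUMNS = ["eq5d_w0", "eq5d_w24"]
_WPAI_FIELDS = ("hours_missed", "hours_worked", "work_impairment_pct",
                "social_impairment_pct", "not_working")
_WPAI_COLUMNS = [f"{f}_w{w}" for w in WEEKS for f in _WPAI_FIELDS]
_RESOURCE_COLUMNS = list(RESOURCE_COUNT_FIELDS) + ["teccu_months"]
_CALPRO_COLUMNS = ["calprotectin_w0", "calprotectin_w24"]

PATIENT_COLUMNS: list[str] = (
    _SCALAR_COLUMNS + _SCORE_COLUMNS + _EQ5D_COLUMNS + _WPAI_COLUMNS
    + _RESOURCE_COLUMNS + _CALPRO_COLUMNS
)


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def _float_cell(row, col, rownum):
    v = _cell(row, col)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise TrialDataError(f"row {rownum}, column {col}: not a number: {v!r}") from None


def _bool_cell(row, col, rownum, default=None):
    v = _cell(row, col)
    if v is None:
        if default is None:
            raise TrialDataError(f"row {rownum}, column {col}: missing boolean")
        return default
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise TrialDataError(f"row {rownum}, column {col}: not a boolean: {v!r}")


def record_to_row(rec: PatientRecord) -> dict:
    row: dict = {
        "patient_id": rec.patient_id, "arm": rec.arm.value, "disease": rec.disease.value,
        "age_years": rec.age_years, "sex": rec.sex.value, "employed": int(rec.employed),
    }
    for idx_name, scores in (("hbi", rec.hbi), ("sccai", rec.sccai), ("pmayo", rec.pmayo)):
        for w in WEEKS:
            row[f"{idx_name}_w{w}"] = scores.get(w)
    row["eq5d_w0"], row["eq5d_w24"] = rec.eq5d.get(0), rec.eq5d.get(24)
    for w in WEEKS:
        wp = rec.wpai[w]
        for f in _WPAI_FIELDS:
            v = getattr(wp, f)
            row[f"{f}_w{w}"] = int(v) if f == "not_working" else v
    for f in _RESOURCE_COLUMNS:
        row[f] = getattr(rec.resources, f)
    row["calprotectin_w0"] = rec.calprotectin.get(0)
    row["calprotectin_w24"] = rec.calprotectin.get(24)
    return row


def row_to_record(row: Mapping, rownum: int) -> PatientRecord:
    pid = _cell(row, "patient_id")
    if pid is None:
        raise TrialDataError(f"row {rownum}, column patient_id: missing")
    try:
        arm = Arm(str(_cell(row, "arm")))
    except ValueError:
        raise TrialDataError(
            f"row {rownum}, column arm: unknown arm code {_cell(row, 'arm')!r}") from None
    try:
        disease = Disease(str(_cell(row, "disease")))
    except ValueError:
        raise TrialDataError(
            f"row {rownum}, column disease: unknown disease code "
            f"{_cell(row, 'disease')!r}") from None
    try:
        sex = Sex(str(_cell(row, "sex")))
    except ValueError:
        raise TrialDataError(
            f"row {rownum}, column sex: unknown sex code {_cell(row, 'sex')!r}") from None
    age = _float_cell(row, "age_years", rownum)
    if age is None:
        raise TrialDataError(f"row {rownum}, column age_years: missing")
    employed = _bool_cell(row, "employed", rownum)

    def scores(idx_name):
        return {w: _float_cell(row, f"{idx_name}_w{w}", rownum) for w in WEEKS}

    wpai = {}
    for w in WEEKS:
        wpai[w] = WPAIResponse(
            hours_missed=_float_cell(row, f"hours_missed_w{w}", rownum),
            hours_worked=_float_cell(row, f"hours_worked_w{w}", rownum),
            work_impairment_pct=_float_cell(row, f"work_impairment_pct_w{w}", rownum),
            social_impairment_pct=_float_cell(row, f"social_impairment_pct_w{w}", rownum),
            not_working=_bool_cell(row, f"not_working_w{w}", rownum, default=not employed),
        )
    res_kwargs = {}
    for f in RESOURCE_COUNT_FIELDS:
        v = _float_cell(row, f, rownum)
        res_kwargs[f] = None if v is None else int(v)
    tm = _float_cell(row, "teccu_months", rownum)
    res_kwargs["teccu_months"] = 0.0 if tm is None else tm
    rec = PatientRecord(
        patient_id=str(pid), arm=arm, disease=disease, age_years=int(age), sex=sex,
        employed=employed,
        hbi=scores("hbi"), sccai=scores("sccai"), pmayo=scores("pmayo"),
        eq5d={0: _float_cell(row, "eq5d_w0", rownum), 24: _float_cell(row, "eq5d_w24", rownum)},
        wpai=wpai, resources=ResourceUse(**res_kwargs),
        calprotectin={0: _float_cell(row, "calprotectin_w0", rownum),
                      24: _float_cell(row, "calprotectin_w24", rownum)},
    )
    try:
        rec.validate()
    except TrialDataError as exc:
        raise TrialDataError(f"row {rownum}: {exc}") from None
    return rec


def read_patients(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[PatientRecord]:
    """Read patient records from CSV, validating every row.

    Missing week-12/24 cells become ``None`` (flagged for imputation), never 0.
    """
    if schema_version != SCHEMA_VERSION:
        raise TrialDataError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"patient file not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing_cols = [c for c in _SCALAR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialDataError(f"{path}: header missing required columns {missing_cols}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        records.append(row_to_record(row, rownum=i + 2))  # +2: header is line 1
    return records


def patients_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([record_to_row(r) for r in records], columns=PATIENT_COLUMNS)
    return df


def write_patients(records: Sequence[PatientRecord], path: str | Path) -> None:
    # %.17g guarantees exact float round trips through the text format
    patients_to_frame(records).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Result writing


def _config_hash(payload) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  metadata: Mapping | None = None) -> dict:
    """Write analysis tables as CSV plus a JSON run-metadata file.

    Returns a manifest mapping logical table names to relative file paths.
    The metadata file records the seed, a config hash and the package version,
    enough to reproduce the numeric outputs bit for bit.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise TrialDataError(f"output directory not writable: {out_dir}: {exc}") from None
    from . import __version__
    meta = dict(metadata or {})
    meta.setdefault("software_version", __version__)
    meta["config_hash"] = _config_hash({k: v for k, v in meta.items() if k != "config_hash"})
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format="%.10g")
        manifest[name] = fname
    meta["files"] = manifest
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    manifest["run_metadata"] = "run_metadata.json"
    return manifest
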