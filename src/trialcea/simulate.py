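"""Synthetic three-arm trial generator.

No patient-level data from the trial were ever released, so this module
generates cohorts with the statistical structure the analysis assumes,
calibrated to the published arm-level summaries: resource-use means/SDs,
remission proportions at baseline and week 24, weeks in remission, EQ-5D
summaries, demographics, and — via an explicit solve — WPAI distributions
such that the expected per-arm societal total cost equals the published
per-arm mean total.

Correlation structure: each patient carries a latent severity score; every
outcome (remission, activity indexes, EQ-5D, WPAI impairment, resource use,
calprotectin) is linked to it through a Gaussian copula, so sicker patients
are simultaneously less often in remission, report lower utility, miss more
work and consume more care.  Marginals: (zero-inflated) negative binomial or
rounded-normal counts (hospitalisations are rare and overdispersed — the
published SDs exceed the means), truncated-normal EQ-5D with a point mass at
1.0 (all arms reach a median of 1.00 at week 24), zero-inflated gamma weekly
absence hours, and beta impairment percentages.

The default missingness mechanism mirrors the trial: a week-24 dropout block
for 3 of 21 telemonitoring-arm patients.  Everything is driven by one seed;
the same seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import published
from .costs import total_cost  # noqa: F401  (re-exported convenience for calibration checks)
from .data import (Arm, Disease, PatientRecord, ResourceUse, Sex, TrialDataError,
                   UnitCostTable, WPAIResponse, default_unit_costs)

#: copula loadings of each outcome family on the latent severity
LOADINGS = {"remission": 0.6, "counts": 0.45, "eq5d": 0.5, "wpai": 0.5, "calpro": 0.4}

#: default structural-zero shares for the overdispersed count marginals
ZERO_INFLATION = {
    "emergency_visits": 0.80, "outpatient_visits": 0.0, "hospital_days": 0.85,
    "surgical_hospital_days": 0.90, "phone_calls": 0.15, "teccu_contacts": 0.0,
}


@dataclass
class EqParams:
    """EQ-5D marginal: point mass at 1.0 plus truncated normal on [-1, 1]."""
    mean: float
    sd: float
    p_ceiling: float


@dataclass
class CountParams:
    mean: float
    sd: float
    zero_inflation: float = 0.0


@dataclass
class WPAIParams:
    p_not_working: float
    hours_worked_mean: float = 35.0
    hours_worked_sd: float = 6.0
    #: weekly hours missed (workers), by visit week
    hours_missed_mean: dict[int, float] = field(default_factory=dict)
    hours_missed_p_zero: float = 0.5
    #: mean impairment-while-working percentage, by visit week
    work_impairment_mean: dict[int, float] = field(default_factory=dict)
    #: mean social-activity impairment percentage, by visit week
    social_impairment_mean: dict[int, float] = field(default_factory=dict)
    impairment_concentration: float = 2.0


@dataclass
class ArmParams:
    remission_prob: dict[int, float]
    eq5d: dict[int, EqParams]
    counts: dict[str, CountParams]
    wpai: WPAIParams
    phone_physician_frac: float = 0.15
    teccu_physician_frac: float = 0.0
    teccu_months: float = 0.0
    p_female: float = 0.5
    p_cd: float = 0.65
    age_mean: float = 40.0
    age_sd: float = 11.0
    age_min: int = 18
    age_max: int = 66
    calpro_median: dict[int, float] = field(default_factory=lambda: {0: 400.0, 24: 180.0})
    calpro_log_sd: float = 1.0

    def validate(self) -> None:
        for wk, p in self.remission_prob.items():
            if not 0 <= p <= 1:
                raise TrialDataError(f"remission_prob[{wk}] must be in [0, 1], got {p}")
        for c in self.counts.values():
            if c.mean < 0 or c.sd < 0 or not 0 <= c.zero_inflation < 1:
                raise TrialDataError("count parameters must be non-negative with "
                                     "zero_inflation in [0, 1)")
        if not 0 <= self.wpai.p_not_working <= 1:
            raise TrialDataError("p_not_working must be in [0, 1]")


@dataclass
class MissingnessConfig:
    """Missingness mechanism applied after generation.

    ``MAR_BY_ARM`` removes the week-24 outcome block (scores, utility, WPAI)
    of ``arm_dropouts[arm]`` randomly chosen patients per arm, emulating
    protocol non-adherence concentrated in one arm.  ``MCAR`` deletes each
    week-12/24 outcome cell independently with probability ``rate``.
    """

    mechanism: str = "MAR_BY_ARM"
    rate: float = 0.0
    arm_dropouts: dict[str, int] = field(
        default_factory=lambda: {"TECCU": published.NONADHERENT_TECCU})

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "MAR_BY_ARM", "NONE"):
            raise TrialDataError(f"unknown missingness mechanism {self.mechanism!r}")
        if not 0 <= self.rate < 1:
            raise TrialDataError(f"missingness rate must be in [0, 1), got {self.rate}")


@dataclass
class GeneratorConfig:
    n_per_arm: int = 21
    arms: dict[str, ArmParams] = field(default_factory=dict)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise TrialDataError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if set(self.arms) != {a.value for a in Arm}:
            raise TrialDataError(f"arms must cover {sorted(a.value for a in Arm)}, "
                                 f"got {sorted(self.arms)}")
        for p in self.arms.values():
            p.validate()
        self.missingness.validate()


# ---------------------------------------------------------------------------
# marginal quantile functions


def _count_ppf(params: CountParams):
    """Quantile function of the count marginal, preserving mean and (approx.) SD."""
    mean, sd, pi = params.mean, params.sd, params.zero_inflation
    if mean <= 0:
        return lambda q: np.zeros_like(np.asarray(q, dtype=float), dtype=int)
    var = sd ** 2
    if var <= mean * 1.05:
        if var < mean * 0.95:  # underdispersed: rounded truncated normal
            def ppf(q):
                v = stats.norm.ppf(q, loc=mean, scale=max(sd, 1e-9))
                return np.maximum(np.rint(v), 0).astype(int)
            return ppf
        return lambda q: stats.poisson.ppf(q, mean).astype(int)
    # zero-inflated negative binomial; shrink pi until the NB part is overdispersed
    while pi > 1e-9:
        lam = mean / (1 - pi)
        v_nb = var / (1 - pi) - pi * lam ** 2
        if v_nb > lam * 1.05:
            break
        pi *= 0.5
    else:
        pi = 0.0
        lam, v_nb = mean, var
    lam = mean / (1 - pi)
    v_nb = var / (1 - pi) - pi * lam ** 2
    r = lam ** 2 / (v_nb - lam)
    p = r / (r + lam)

    def ppf(q):
        q = np.asarray(q, dtype=float)
        out = np.zeros(q.shape, dtype=int)
        nz = q >= pi
        out[nz] = stats.nbinom.ppf((q[nz] - pi) / (1 - pi), r, p).astype(int)
        return out
    return ppf


def _eq5d_value(q: np.ndarray, params: EqParams) -> np.ndarray:
    """Mixture quantile: top ``p_ceiling`` mass at 1.0, rest truncated normal."""
    base_mean, base_sd = _eq5d_base(params)
    a, b = (-1 - base_mean) / base_sd, (1 - base_mean) / base_sd
    q = np.asarray(q, dtype=float)
    out = np.ones_like(q)
    lower = q < (1 - params.p_ceiling)
    qq = np.clip(q[lower] / (1 - params.p_ceiling), 1e-9, 1 - 1e-9)
    out[lower] = stats.truncnorm.ppf(qq, a, b, loc=base_mean, scale=base_sd)
    return out


def _eq5d_base(params: EqParams) -> tuple[float, float]:
    """Truncated-normal location/scale so the mixture matches the target mean/SD."""
    pc = params.p_ceiling
    mu, sd = params.mean, params.sd
    for _ in range(20):
        m0 = (mu - pc) / (1 - pc)
        s2 = (mu ** 2 + sd ** 2 - pc) / (1 - pc) - m0 ** 2
        if s2 > 1e-4 and m0 < 1:
            return m0, float(np.sqrt(s2))
        pc *= 0.8  # ceiling mass too large for the target moments; shrink it
    return min(mu, 0.95), max(sd, 0.05)


def _beta_ppf(q, mean_pct: float, concentration: float) -> np.ndarray:
    m = np.clip(mean_pct / 100.0, 1e-3, 1 - 1e-3)
    a, b = m * concentration, (1 - m) * concentration
    return 100.0 * stats.beta.ppf(q, a, b)


# ---------------------------------------------------------------------------
# generation


def _corr_uniform(rng: np.random.Generator, z: np.ndarray, rho: float) -> np.ndarray:
    """Uniforms with Gaussian-copula correlation rho to the latent severity z."""
    x = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(z.shape)
    return stats.norm.cdf(x)


def _scores_for(rng, disease: Disease, in_remission: bool):
    """Activity-index scores consistent with a remission status."""
    if disease == Disease.CD:
        hbi = (rng.choice(5, p=[0.3, 0.25, 0.2, 0.15, 0.1]) if in_remission
               else 5 + rng.poisson(3))
        return float(hbi), None, None
    if in_remission:
        sccai = int(rng.choice(3, p=[0.5, 0.3, 0.2]))
        pmayo = int(rng.choice(3, p=[0.5, 0.3, 0.2]))
    else:
        sccai = int(3 + rng.poisson(3))
        pmayo = int(min(3 + rng.poisson(2), 9))
    return None, float(sccai), float(pmayo)


def generate_arm(rng: np.random.Generator, arm: Arm, params: ArmParams,
                 n: int, id_offset: int = 0) -> list[PatientRecord]:
    params.validate()
    records = []
    for i in range(n):
        z = rng.standard_normal()
        zv = np.array([z])
        sex = Sex.F if rng.random() < params.p_female else Sex.M
        disease = Disease.CD if rng.random() < params.p_cd else Disease.UC
        a, b = ((params.age_min - params.age_mean) / params.age_sd,
                (params.age_max - params.age_mean) / params.age_sd)
        age = int(round(stats.truncnorm.rvs(a, b, loc=params.age_mean,
                                            scale=params.age_sd, random_state=rng)))
        employed = rng.random() >= params.wpai.p_not_working

        hbi, sccai, pmayo = {}, {}, {}
        for wk in (0, 12, 24):
            q = _corr_uniform(rng, zv, LOADINGS["remission"])[0]
            rem = q < params.remission_prob[wk]
            hbi[wk], sccai[wk], pmayo[wk] = _scores_for(rng, disease, rem)

        eq5d = {}
        for wk in (0, 24):
            q = 1.0 - _corr_uniform(rng, zv, LOADINGS["eq5d"])[0]
            eq5d[wk] = float(np.clip(_eq5d_value(np.array([q]), params.eq5d[wk])[0], -1, 1))

        counts = {}
        for res, cp in params.counts.items():
            q = _corr_uniform(rng, zv, LOADINGS["counts"])[0]
            counts[res] = int(_count_ppf(cp)(np.array([q]))[0])
        phone_phys = int(rng.binomial(counts["phone_calls"], params.phone_physician_frac))
        teccu_phys = int(rng.binomial(counts["teccu_contacts"], params.teccu_physician_frac))
        resources = ResourceUse(
            emergency_visits=counts["emergency_visits"],
            outpatient_visits=counts["outpatient_visits"],
            hospital_days=counts["hospital_days"],
            surgical_hospital_days=counts["surgical_hospital_days"],
            phone_contacts_nurse=counts["phone_calls"] - phone_phys,
            phone_contacts_physician=phone_phys,
            teccu_contacts_nurse=counts["teccu_contacts"] - teccu_phys,
            teccu_contacts_physician=teccu_phys,
            teccu_months=params.teccu_months if arm == Arm.TECCU else 0.0,
        )

        wpai = {}
        wp = params.wpai
        hours_worked = (float(np.clip(rng.normal(wp.hours_worked_mean, wp.hours_worked_sd),
                                      5.0, 60.0)) if employed else 0.0)
        for wk in (0, 12, 24):
            q_soc = _corr_uniform(rng, zv, LOADINGS["wpai"])[0]
            social = float(_beta_ppf(np.array([q_soc]), wp.social_impairment_mean[wk],
                                     wp.impairment_concentration)[0])
            if not employed:
                wpai[wk] = WPAIResponse(hours_missed=0.0, hours_worked=0.0,
                                        work_impairment_pct=0.0,
                                        social_impairment_pct=social, not_working=True)
                continue
            q_hm = _corr_uniform(rng, zv, LOADINGS["wpai"])[0]
            p0 = wp.hours_missed_p_zero
            if q_hm < p0 or wp.hours_missed_mean[wk] <= 0:
                hm = 0.0
            else:
                mean_nz = wp.hours_missed_mean[wk] / (1 - p0)
                hm = float(stats.expon.ppf((q_hm - p0) / (1 - p0), scale=mean_nz))
            q_wi = _corr_uniform(rng, zv, LOADINGS["wpai"])[0]
            wimp = float(_beta_ppf(np.array([q_wi]), wp.work_impairment_mean[wk],
                                   wp.impairment_concentration)[0])
            wpai[wk] = WPAIResponse(hours_missed=min(hm, 80.0), hours_worked=hours_worked,
                                    work_impairment_pct=wimp,
                                    social_impairment_pct=social, not_working=False)

        calpro = {}
        for wk in (0, 24):
            q = _corr_uniform(rng, zv, LOADINGS["calpro"])[0]
            calpro[wk] = float(stats.lognorm.ppf(
                q, s=params.calpro_log_sd, scale=params.calpro_median[wk]))

        rec = PatientRecord(
            patient_id=f"{arm.value}-{id_offset + i + 1:04d}", arm=arm, disease=disease,
            age_years=max(age, 18), sex=sex, employed=employed,
            hbi=hbi, sccai=sccai, pmayo=pmayo, eq5d=eq5d, wpai=wpai,
            resources=resources, calprotectin=calpro,
        )
        rec.validate()
        records.append(rec)
    return records


def apply_missingness(records: list[PatientRecord], config: MissingnessConfig,
                      rng: np.random.Generator) -> list[PatientRecord]:
    """Delete outcome cells in place according to the configured mechanism."""
    config.validate()
    if config.mechanism == "NONE" or (config.mechanism == "MCAR" and config.rate == 0):
        return records

    def blank_week24(rec: PatientRecord) -> None:
        rec.hbi[24] = rec.sccai[24] = rec.pmayo[24] = None
        rec.eq5d[24] = None
        w = rec.wpai[24]
        w.hours_missed = w.hours_worked = None
        w.work_impairment_pct = w.social_impairment_pct = None
        if not rec.employed:
            w.hours_worked = 0.0

    if config.mechanism == "MAR_BY_ARM":
        for arm_name, n_drop in config.arm_dropouts.items():
            idx = [i for i, r in enumerate(records) if r.arm == Arm(arm_name)]
            if n_drop > len(idx):
                raise TrialDataError(f"cannot drop {n_drop} patients from arm {arm_name} "
                                     f"of size {len(idx)}")
            for i in rng.choice(idx, size=n_drop, replace=False):
                blank_week24(records[i])
        return records

    # MCAR on week-12/24 outcome cells
    for rec in records:
        for wk in (12, 24):
            if rng.random() < config.rate:
                if rec.disease == Disease.CD:
                    rec.hbi[wk] = None
                else:
                    rec.sccai[wk] = rec.pmayo[wk] = None
            if wk == 24 and rng.random() < config.rate:
                rec.eq5d[24] = None
            w = rec.wpai[wk]
            if rec.employed and rng.random() < config.rate:
                w.hours_missed = w.hours_worked = w.work_impairment_pct = None
            if rng.random() < config.rate:
                w.social_impairment_pct = None
    return records


def generate_trial(config: GeneratorConfig | None = None,
                   seed: int | None = None) -> list[PatientRecord]:
    """Generate one synthetic trial (n_per_arm records per arm), seeded."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        config.seed if seed is None else seed))
    records: list[PatientRecord] = []
    for arm in Arm:
        records.extend(generate_arm(rng, arm, config.arms[arm.value], config.n_per_arm))
    apply_missingness(records, config.missingness, rng)
    return records


# ---------------------------------------------------------------------------
# calibration to the published summaries


def expected_wage(params: ArmParams, unit_costs: UnitCostTable) -> float:
    """Exact expected hourly wage under the arm's sex/age distribution."""
    from .data import WAGE_AGE_BANDS
    a, b = ((params.age_min - params.age_mean) / params.age_sd,
            (params.age_max - params.age_mean) / params.age_sd)
    dist = stats.truncnorm(a, b, loc=params.age_mean, scale=params.age_sd)
    w = 0.0
    for sex, p_sex in ((Sex.F, params.p_female), (Sex.M, 1 - params.p_female)):
        rates = unit_costs.wage_table[sex.value]
        for (lo, hi), rate in zip(WAGE_AGE_BANDS, rates):
            p_band = dist.cdf(hi - 0.5) - dist.cdf(lo - 0.5)
            w += p_sex * p_band * rate
    return w


def _expected_structural_costs(arm: str, params: ArmParams,
                               unit_costs: UnitCostTable) -> tuple[float, float]:
    """Expected (health-care + equipment, structurally derived productivity) cost."""
    c = params.counts
    teccu_rate = ((1 - params.teccu_physician_frac)
                  * unit_costs.contact_minutes * unit_costs.nurse_salary_per_min
                  + params.teccu_physician_frac
                  * unit_costs.contact_minutes * unit_costs.physician_salary_per_min)
    phone_rate = ((1 - params.phone_physician_frac) * unit_costs.phone_call_nurse
                  + params.phone_physician_frac * unit_costs.phone_call_physician)
    hc = (c["emergency_visits"].mean * unit_costs.emergency_visit
          + c["outpatient_visits"].mean * unit_costs.outpatient_visit
          + c["hospital_days"].mean * unit_costs.hospital_day
          + c["surgical_hospital_days"].mean * unit_costs.surgical_hospital_day
          + c["phone_calls"].mean * phone_rate
          + c["teccu_contacts"].mean * teccu_rate
          + params.teccu_months * unit_costs.teccu_rental_per_patient_month)
    ew = expected_wage(params, unit_costs)
    visits = c["emergency_visits"].mean + c["outpatient_visits"].mean
    structural = (visits * unit_costs.visit_absence_hours * ew
                  + c["phone_calls"].mean * unit_costs.patient_phone_minutes / 60.0 * ew
                  + c["teccu_contacts"].mean * unit_costs.teccu_patient_minutes / 60.0
                  * unit_costs.leisure_hour)
    return hc, structural


def default_config(unit_costs: UnitCostTable | None = None,
                   seed: int = 0) -> GeneratorConfig:
    """Generator configuration calibrated to the published arm summaries.

    Resource-use marginals match the published mean/SD units; remission
    probabilities come from the published counts (week 12 backed out of the
    published weeks-in-remission means); EQ-5D marginals match the published
    week-24 mean/SD and mean improvement with a ceiling mass at 1.0; WPAI
    absence/impairment means are solved so that the expected societal total
    cost per arm equals the published per-arm mean total (the published
    per-category productivity means are mutually inconsistent with the
    published totals, so the totals win and absenteeism/presenteeism are
    scaled proportionally).
    """
    uc = unit_costs or default_unit_costs()
    arms: dict[str, ArmParams] = {}
    for arm in ("CONTROL", "NT", "TECCU"):
        demo = published.DEMOGRAPHICS[arm]
        units = published.RESOURCE_UNITS[arm]
        counts = {res: CountParams(mean=m, sd=s, zero_inflation=ZERO_INFLATION[res])
                  for res, (m, s) in units.items()}
        rc = published.REMISSION_COUNTS[arm]
        n = demo["n"]
        p0, p24 = rc["w0"] / n, rc["w24"] / n
        p12 = float(np.clip(published.WEEKS_IN_REMISSION[arm][0] / 12.0 - p24, 0.0, 1.0))
        eq = published.EQ5D[arm]
        w24_mean, w24_sd = eq["mean_w24"]
        imp_mean, _ = eq["mean_improvement"]
        eq5d = {
            0: EqParams(mean=w24_mean - imp_mean, sd=0.15, p_ceiling=0.20),
            24: EqParams(mean=w24_mean, sd=w24_sd, p_ceiling=0.55),
        }
        age_lo, age_hi = demo["age_range"]
        params = ArmParams(
            remission_prob={0: p0, 12: p12, 24: p24},
            eq5d=eq5d, counts=counts,
            wpai=WPAIParams(p_not_working=demo["not_working"] / n),
            phone_physician_frac=published.PHONE_PHYSICIAN_FRACTION[arm],
            teccu_physician_frac=(published.TECCU_PHYSICIAN_FRACTION
                                  if arm == "TECCU" else 0.0),
            teccu_months=6.0 if arm == "TECCU" else 0.0,
            p_female=demo["female"] / n, p_cd=demo["cd"] / n,
            age_mean=demo["age_median"], age_sd=11.0,
            age_min=max(int(age_lo) - 1, 18), age_max=int(age_hi) + 2,
            calpro_median={0: published.CALPROTECTIN_MEDIANS[arm]["w0"],
                           24: published.CALPROTECTIN_MEDIANS[arm]["w24"]},
        )
        # solve WPAI absence/impairment means against the published total cost
        hc, structural = _expected_structural_costs(arm, params, uc)
        total_target = published.COST_MEANS[arm]["total"][0]
        indirect_target = max(total_target - hc - structural, 0.0)
        abs_pub = published.COST_MEANS[arm]["absenteeism"][0]
        pres_pub = published.COST_MEANS[arm]["presenteeism"][0]
        share_abs = abs_pub / (abs_pub + pres_pub)
        abs_target = indirect_target * share_abs
        pres_target = indirect_target * (1 - share_abs)
        ew = expected_wage(params, uc)
        p_emp = 1 - params.wpai.p_not_working
        # E[absence cost] = P(employed) * weekly_hours * 24 weeks * wage
        hm_weekly = abs_target / (p_emp * ew * 24.0)
        # E[presenteeism cost] = P(employed) * pct/100 * hours_worked * 24 * wage
        wi_mean = 100.0 * pres_target / (p_emp * ew * 24.0 * params.wpai.hours_worked_mean)
        wi_mean = float(np.clip(wi_mean, 0.5, 95.0))
        # baseline (week 0) is never costed; disease is more active there, so
        # double the post-baseline means (capped for percentages)
        params.wpai.hours_missed_mean = {0: 2.0 * hm_weekly, 12: hm_weekly, 24: hm_weekly}
        params.wpai.work_impairment_mean = {0: min(2.0 * wi_mean, 95.0), 12: wi_mean,
                                            24: wi_mean}
        params.wpai.social_impairment_mean = {0: 40.0, 12: 25.0, 24: 20.0}
        arms[arm] = params
    return GeneratorConfig(n_per_arm=21, arms=arms,
                           missingness=MissingnessConfig(), seed=seed)


def expected_total_cost(params: ArmParams, arm: str, unit_costs: UnitCostTable) -> float:
    """Closed-form expected societal total cost per patient for an arm config."""
    hc, structural = _expected_structural_costs(arm, params, unit_costs)
    ew = expected_wage(params, unit_costs)
    p_emp = 1 - params.wpai.p_not_working
    absent = p_emp * ew * 12.0 * (params.wpai.hours_missed_mean[12]
                                  + params.wpai.hours_missed_mean[24])
    pres = (p_emp * ew * 12.0 * params.wpai.hours_worked_mean / 100.0
            * (params.wpai.work_impairment_mean[12] + params.wpai.work_impairment_mean[24]))
    return hc + structural + absent + pres


def worked_example_fixture() -> dict:
    """The published group-level summaries (see :mod:`trialcea.published`)."""
    return published.worked_example_fixture()


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)
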