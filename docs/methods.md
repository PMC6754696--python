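# Methods

This note documents the model, the costing and effect conventions, the
imputation and bootstrap machinery, the synthetic-data generator and its
calibration, and the numerical choices made where the design was genuinely
open.

## Study setting

A 24-week, three-arm parallel randomized trial in complex IBD: Web
telemonitoring (TECCU), nurse-assisted telephone care (NT), and standard
face-to-face care (CONTROL), 21 patients per arm, recruited at treatment
initiation with immunosuppressants and/or biologics.  The economic evaluation
takes the societal perspective: health-system costs, platform equipment
costs, and patients' productivity and leisure losses.  Costs are in EUR at
trial-period Spanish rates; a USD conversion factor of 1.09465 (the ratio of
every published €/US$ pair) is applied at report time only.  At a 24-week
horizon neither costs nor effects are discounted, and productivity losses are
valued by the human-capital approach (gross wage for all time lost).

## Cost model

Per patient over 24 weeks, with unit costs from the packaged table
(`trialcea.data.default_unit_costs`):

| category | formula |
|---|---|
| emergency / outpatient / hospital / surgical | count × unit rate (189 / 40.02 / 310.17 / 378 €) |
| telephone contacts | count × 15 € (nurse) or 21.47 € (physician) |
| telemonitoring contacts | count × 8 min × salary/min (0.21 nurse, 0.38 physician) |
| equipment | patient-months × 3.99 € (6 months in the TECCU arm) |
| absenteeism | Σᵥ 12 wk × weekly WPAI-Q2 hours × wage(sex, age) |
| presenteeism | Σᵥ 12 wk × min(Q5/100 × Q4, Q4) hours × wage |
| visit absence | (outpatient + emergency visits) × 3.3 h × wage |
| call absence | telephone contacts × 10 min × wage |
| telemonitoring leisure | platform contacts × 5 min × 9.18 €/h |
| social-impairment leisure | Σᵥ 12 wk × Q6/100 × weekly leisure hours × 9.18 €/h |

Conventions and their reasons:

* **Piecewise-constant WPAI expansion.** WPAI has a 7-day recall but was
  administered at weeks 0/12/24 only; the week-12 response covers weeks 1–12
  and the week-24 response weeks 13–24.  This is the simplest defensible
  rule; it is isolated in one operation (`costs.interval_expand`) so it can
  be swapped.  Baseline WPAI is a covariate only and is never costed.
* **Presenteeism hours are capped at hours worked** — impairment cannot lose
  more time than was worked.
* **Visit/call time is valued at the wage for all patients**, employed or
  not.  The published per-arm "absenteeism for medical visits" means equal
  (all-patients mean visits) × 3.3 h × (all-patients mean wage), which fixes
  this convention.
* **Patient-side contact durations.** The published tables imply 5 min of
  patient leisure per telemonitoring contact (25.37 € per patient ÷ 33.15
  contacts ÷ 9.18 €/h) and roughly 10 min per telephone call; both are
  config (`teccu_patient_minutes`, `patient_phone_minutes`).
* **Weekly leisure hours at risk default to 0.** The published cost tables
  contain no social-impairment (WPAI Q6) cost row and their totals exclude
  it, so the packaged default keeps the category at zero while the operation
  and a config hook (`leisure_hours_weekly`) remain available.
* **Wage table.** The national sex × age wage values are not public; the
  package ships a plausible sex × 10-year-band grid spanning the published
  12.04–25.23 €/h bounds, user-replaceable in the unit-cost YAML.
* **Inflation correction** is a single configurable multiplier (default 1);
  the price-index factors used originally are not public.
* Full precision is kept internally; printed-table comparisons round half
  away from zero at the displayed precision (`util.round_half_up`), which
  reproduces cells like 23.94/26.21 without accumulating error.

## Effect model

Remission: HBI ≤ 4 (Crohn), SCCAI ≤ 2 *and* partial Mayo ≤ 2 (ulcerative
colitis; if only one index is recorded it decides).  The primary effect is
the within-arm change in remission proportion between weeks 0 and 24.  Weeks
in remission uses the same piecewise-constant expansion as the cost model
(week-12 status × 12 + week-24 status × 12).

QALYs follow the trial's *gained-QALY* convention,
ΔQALY = (U₂₄ − U₀) × 0.5 years, which reproduces the published arithmetic
(0.184 × 6/12 = 0.092; 0.175 × 6/12 = 0.088).  An area-under-the-curve
alternative ((U₀ + U₂₄)/2 × 0.5) is available behind `qaly(..., auc=True)`
for sensitivity use.  Group-level EQ-5D worked examples use medians, as
published; the bootstrap resamples patients and therefore differences group
means.

## Missing data

Outcomes may be missing at weeks 12/24 (scores, utility, WPAI, resource
counts); arm, disease and demographics are always observed.  Imputation is a
native bootstrap-EM multivariate-normal imputer (m = 5 by default): each
imputation bootstraps the records, runs EM to the MVN maximum-likelihood mean
and covariance (missingness patterns handled by conditional expectations,
with a small ridge — 5% of the mean diagonal divided by n — for stability),
then fills the original missing cells with conditional-normal draws.
Bootstrapping the parameters propagates estimation uncertainty between
imputations.  Costs, counts and hours are imputed on a log1p scale and
back-transformed (counts rounded to non-negative integers); percentages and
utilities are clipped to their support.  Treatment arm and baseline values
are columns of the model, so imputation respects group structure — important
because dropout concentrates in one arm.  Observed cells are never altered.
The exact settings of the original EM-with-bootstrapping software are not
public; the variant implemented here is recorded in
`ImputationSet.method_tag`.

Point estimates are pooled by Rubin's rules: pooled estimate = mean of the m
estimates; total variance = mean within-imputation variance +
(1 + 1/m) × between-imputation variance.

## Bootstrap engine

For each ordered contrast and each of the m imputed datasets, B = 1000
replicates resample n = 21 patients with replacement within each arm and
record (ΔC, ΔE) of the group summaries; the m × B = 5000 pooled draws feed
all summaries (Rubin pooling applies to the point estimates of means; the
median ICER and its percentile interval are taken over the pooled draws).

* **ICER** = ΔC/ΔE, undefined (NaN) at ΔE = 0; undefined draws are excluded
  from ratio summaries but retained in the plane and the acceptability
  curve.  Ratio summaries require ≥ 100 defined draws.
* **Acceptability criterion: net monetary benefit**, cost-effective at λ iff
  λ·ΔE − ΔC > 0.  The ratio-threshold rule is sign-ambiguous for ΔE < 0; NMB
  is well defined everywhere, gives CEAC(0) = P(ΔC < 0) exactly, and
  reproduces the published *decreasing* QALY acceptability curves that arise
  when most draws carry no health gain (the curve tends to P(ΔE > 0) as
  λ → ∞).
* **Quadrants** use strict inequalities for the favourable side: dominant is
  ΔE > 0 and ΔC < 0; boundary draws (ΔE = 0 or ΔC = 0) count to the
  unfavourable side, so the four probabilities sum to 1 exactly and a
  boundary draw is never dominant.  Boundaries are measure-zero for
  continuous costs; the rule only exists for reproducibility.
* **Random-number discipline.** Each (imputation, replicate) pair derives its
  own substream from the master seed by counter
  (`SeedSequence(seed, spawn_key=(d, b))`), so summaries are independent of
  draw order and enlarging B extends the draw set without reshuffling earlier
  replicates.  Sensitivity scenarios reuse identical resample indices
  (common random numbers), so scenario curves differ only through the cost
  scaling.

## Sensitivity analysis

Scenarios rescale the health-care block (including equipment) and the
productivity/leisure block by independent multipliers, default one-at-a-time
over ±60% ({0.4, 1.0, 1.6}); both one-at-a-time and joint grids are
supported since the original report is ambiguous on this point.  With equal
multipliers on both blocks the sign of ΔC is invariant, hence so is CEAC(0).

## Synthetic-data generator

Each patient carries a latent severity variable; every outcome is linked to
it through a Gaussian copula (loadings: remission 0.6, EQ-5D 0.5, WPAI 0.5,
resource counts 0.45, calprotectin 0.4), so remission, quality of life, work
impairment and resource use are mutually consistent within a patient.
Marginals:

* **Resource counts**: zero-inflated negative binomial, moment-matched to
  the published per-arm mean/SD units (hospitalisations are rare and
  overdispersed; a Poisson cannot reproduce SD > mean).  Underdispersed
  counts (e.g. scheduled outpatient visits, SD < mean) use a rounded
  truncated normal; near-equidispersed ones a Poisson.  Telephone and
  telemonitoring contacts are split nurse/physician by the fractions implied
  by the published per-contact costs.
* **EQ-5D**: truncated normal on [−1, 1] plus a point mass at 1.0 (every arm
  reaches a median of 1.00 at week 24); the mixture is solved to match the
  published week-24 mean/SD, and the baseline mean is week-24 mean minus the
  published mean improvement.
* **Remission**: marginal probabilities at weeks 0/24 are the published
  counts ÷ 21; the week-12 probability is backed out of the published weeks-
  in-remission means via the piecewise-constant rule (p₁₂ = weeks/12 − p₂₄).
  Activity-index scores are then drawn consistently with the status.
* **WPAI**: employment per the published not-working fractions; weekly
  absence hours are zero-inflated exponential and impairment percentages are
  beta, with means *solved* so that the expected per-arm societal total cost
  equals the published per-arm mean total (807/992/1066 €) given the
  expected wage under the arm's sex/age distribution (computed exactly).
  This solve is necessary because the published per-category productivity
  means are mutually inconsistent with the published totals (the TECCU rows
  sum to ~597 € against a printed productivity total of 407 €); the totals —
  which drive every downstream comparison — win, and
  absenteeism/presenteeism are scaled proportionally.
* **Missingness**: default MAR-by-arm, removing the week-24 outcome block of
  3 random TECCU-arm patients (the trial's non-adherent count); MCAR at a
  configurable cell rate is available for imputation studies.

What the generator does *not* emulate: real within-patient cost/effect joint
distributions beyond the single-factor copula, visit-schedule differences by
drug regimen, seasonal effects, or any attempt to reconstruct actual
patients.  Passing tests therefore demonstrate that the pipeline is correct
and calibrated to the published arm summaries, not that it reproduces the
unreleased patient-level data: the published bootstrap medians/CIs (e.g. the
€−1005 median ICER, the 79.96% dominant probability) depend on those data
and are treated as qualitative calibration only.

## Numerical and testing choices

* Tolerances in stochastic tests are stated in Monte-Carlo standard errors
  (typically 3 SE) at the simulation sizes used: calibration checks run at
  3000 patients per arm; the enumeration oracle compares exhaustive 4-patient
  resampling (256² combinations) against 6000 bootstrap draws; the Gaussian
  CEAC oracle uses 5000 draws; Rubin-interval coverage uses 200 replicates.
* EM convergence: max |Δ parameter| < 1e-6, ≤ 200 iterations; a bootstrap
  resample that loses a whole column is redrawn (≤ 20 attempts).
* Degenerate inputs raise `TrialDataError` with the offending row/column
  named; validation never silently coerces (blank cells are missing, not 0).
* Determinism: one master seed drives generation, imputation and bootstrap;
  equal seeds give byte-identical CSV outputs.

## Known limitations

* The wage grid, leisure-hours base, patient-side call durations and
  inflation factors are configurable stand-ins for values the trial report
  cites but does not print.
* The EQ-5D tariff itself is out of scope: utilities enter pre-computed.
* No MNAR sensitivity modelling; no Fieller or BCa intervals (the published
  analysis used percentile intervals); contrasts are pairwise, with no
  three-way frontier.
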