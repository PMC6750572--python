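# Methods

## Problem and design

The package asks whether a sex-specific Cox-form absolute-risk equation,
fitted to a general primary-care population, under-predicts cardiovascular
(CVD) events among people with severe mental illness (SMI), operationalized
as any face-to-face specialist mental-health service contact in the five
years before the index CVD risk assessment.  The real linkage of a
risk-assessment cohort to national mental-health service records is not
shareable, so the pipeline is validated by *parameter recovery*: a
synthetic cohort is generated with a known excess event risk in the exposed
group, and the analysis must recover that excess as its calibration
statistic.

## Risk equation

Per sex, absolute risk at horizon *h* (5 years) is
`1 − S₀(h)^exp(LP)` with `LP = Σ βⱼ(xⱼ − cⱼ)` plus optional pairwise
interactions.  Predictors: age, smoking (past/current indicators vs never),
diabetes, atrial fibrillation, family history of premature CVD, systolic
blood pressure, TC:HDL ratio, blood-pressure-lowering / lipid-lowering /
antithrombotic medication, prioritized ethnicity (indicators vs the
European/other reference), and deprivation quintile.  Equations are
external JSON/YAML documents with a schema version, so a production
coefficient set can be dropped in without code changes.  The bundled
default is an illustrative, synthetic coefficient set — it is not a
published equation — tuned only so that a screening-age cohort gets
realistic risk magnitudes (cohort mean ≈ 3%, top decile ≈ 8–15% at 5
years).  Whether production equations of this family include interaction
terms is unknown to us; the schema supports them and the default uses none.

## Synthetic cohort generator

The generator emulates, per its defaults:

- **Exposure structure**: SMI prevalence 5.8%; functional-psychosis
  (F20–F31) fraction of the exposed 15.5%; contact diagnosis codes missing
  completely at random at the contact level with probability 0.362.
  Psychosis persons always carry at least one F20–F31-coded contact (a
  configurable fraction dated after the index assessment, exercising the
  any-date diagnosis rule); non-psychosis persons never do, so person-level
  ascertainment from contacts is exact by construction.
- **Sex composition**: the published source tables are internally
  inconsistent about the share of women among the exposed (a printed count
  and percentage that disagree), so the generator applies one `sex_split`
  to exposed and unexposed alike rather than matching either figure.
- **Entry and follow-up**: index dates are staggered over a 12.2-year
  study window (2004-10-20 to 2016-12-31).  Uniform entry would give a
  mean administrative follow-up of 6.1 years, which cannot reconcile a
  12.2-year maximum with the ~4.5-year mean the design targets; real
  recruitment into such platforms accelerates over time.  Entry is
  therefore Beta-shaped (density ∝ x^(a−1), default a = 1.6), calibrated
  once against the ~4.5-year mean together with the non-CVD death hazard
  (exponential, 0.005/year).  Follow-up is exact days / 365.25.
- **Risk factors**: age (normal, sex-specific means, SMI persons ~5 years
  younger), SBP/DBP, TC:HDL, BMI (with 19.7% missingness), smoking
  (higher current-smoking among SMI), diabetes (elevated in the psychosis
  subgroup), deprivation and ethnicity distributions skewed for the SMI
  group — all at magnitudes typical of published cohort description
  tables.  Prior CVD (12%) and renal failure (1.2%) flags, a small rate of
  out-of-age-range persons, missing smoking/cholesterol values, decoy
  contacts (older than the window, or non-face-to-face) exist only to
  exercise the eligibility and ascertainment filters.
- **Outcomes**: baseline survival is Weibull-shaped between 0 and the
  horizon, `S₀(t) = S₀(h)^((t/h)^k)` with shape k = 1.15, anchored at the
  equation's S₀(h).  Event times are drawn by inverse transform from the
  true cumulative risk; non-CVD death is an independent exponential time;
  administrative censoring runs from entry to study end capped at 12.2
  years.  `event_type` records whichever comes first.

Two excess parameterizations are provided because the analysis measures a
risk-scale ratio while cohort modelling conventionally works on hazards:
`risk_ratio` mode (default; `R_true = min(1, m·R_eq)`) makes the
observed:predicted ratio equal the generating factor m by construction and
is what the recovery checks use; `hazard_ratio` mode (m multiplies
exp(LP)) is the more mechanistically conventional alternative and
approaches the same ratio only for small risks.  Default factors are 1.64
(women) and 1.29 (men).

What the generator does **not** emulate: real ICD-10-AM hospitalisation
coding, drug dispensing, emigration-based loss to follow-up (folded into
administrative censoring), within-person correlation of risk factors
beyond an age–SBP trend, secular trends in treatment, or informative
censoring.  Passing recovery tests therefore show that the *pipeline*
measures what it claims on data with this structure — not that any
particular published equation is miscalibrated on real data.

## Cohort construction

Eligibility: age 30–74 inclusive at index, no prior CVD (including heart
failure) or renal failure, non-missing smoking status and TC:HDL.
Exclusions are counted in that fixed order, each person once at the first
failing rule, so stage counts telescope exactly.  Exposure uses the
half-open window `[index − 5y, index)` on calendar dates — "prior to" the
assessment excludes same-day contacts — and only inpatient or face-to-face
community settings qualify.  Psychosis requires any F20–F31 code on any
contact at any date (diagnosis completeness, not exposure timing, is the
limiting factor for this subgroup); code matching uses the two-digit ICD-10
family and ignores sub-codes; malformed codes are logged and treated as
missing.  Prioritized ethnicity resolves multiple raw records as
Māori > Pacific > Indian > Chinese/other Asian > European/other,
independent of record order.

## Survival estimation

Kaplan–Meier curves (lifelines' product-limit estimator behind the
package's `SurvivalCurve` surface) with Greenwood variance and
log(−log)-transformed 95% bands, which respect the (0,1) range; the
transform used by the original figures is not stated, so this standard
bounded choice is documented rather than guessed.  Observed risk at the
horizon is `1 − Ŝ(5)` with the right-continuous step convention; queries
beyond the last follow-up warn and return the last estimate.

Age adjustment: the original analysis does not state its method, so the
package uses direct standardization — transparent and exactly testable —
over 10-year bands (30–39 … 60–69, closing band 70–74; bands cover the
real line as [lo, hi+1)), weighting band-specific Kaplan–Meier incidence
by the whole eligible cohort's band composition.  Variances combine as the
weighted sum of band Greenwood variances (delta method for a linear
combination).  An empty group×band cell keeps its reference weight,
contributes zero incidence, and is flagged in `missing_strata`; a group
with zero events yields a flat zero curve.

## Calibration

Deciles are rank-based with stable (risk, person_id) tie-breaking; sizes
differ by at most one.  Deciles are formed within each analysis population
separately (SMI, non-SMI, and within sex for the sex-specific tables);
combined-sex deciles are formed on the pooled population.  Per decile:
mean predicted risk, Kaplan–Meier observed risk at the horizon with its
CI, and the ratio observed/predicted.  The headline statistic is the
unweighted arithmetic mean of the ten ratios (the direction is fixed so
that values > 1 mean under-prediction); a person-weighted mean is also
emitted for comparison.  A decile with zero events keeps ratio 0 and is
flagged rather than dropped.

## Numerical and reproducibility choices

- All randomness flows from one integer seed through numpy Generators;
  identical (config, seed) pairs regenerate byte-identical CSV artifacts,
  and the run manifest records SHA-256 digests of every output.
- S₀(h) = 1 is treated as a null hazard (no events) rather than a
  degenerate logarithm.
- Event times are rounded to microyear precision for tidy CSVs; ties
  between event, death and censoring times are broken in that order (a
  measure-zero event).
- Percentages in descriptive tables round half-up to one decimal, matching
  the house style of published cohort tables; the "elevated BP" predicate
  is implemented exactly as the source table footnote defines it
  (SBP > 120 mmHg or DBP > 90 mmHg), unusual as that threshold is.

## Problem sizes

Recovery runs use 50,000-person single-sex all-exposed cohorts (roughly
41,000 eligible after exclusions, ~10 seconds each for the full pipeline);
the follow-up calibration uses the default 100,000-person cohort; unit and
property tests use 4,000–40,000-person cohorts.  Monte-Carlo tolerances in
tests are set at 3 standard errors of the quantity under test (with a
Šidák correction where ten deciles are tested jointly).

## Known limitations

- The decile mean ratio is a crude calibration summary: it ignores decile
  width and censoring-induced variance differences between deciles, and an
  unweighted mean over deciles is not a person-weighted miscalibration
  estimate.
- Direct standardization with sparse strata (small exposed groups at old
  ages) can be noisy; the flagged-missing-stratum convention biases a
  group's adjusted curve toward zero where a band is truly empty.
- In `risk_ratio` mode the excess is constant over time and covariates; in
  real cohorts the excess likely varies by age, sex and diagnosis.
- The generator's covariates are mutually independent apart from the
  age–SBP trend and the exposure-linked shifts, which understates the
  correlation structure of real risk factors.
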