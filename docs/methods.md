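# Methods

## Problem and estimand

A surgical episode either develops venous thromboembolism (VTE) within 90
days of surgery or it does not. The quantity of interest is the *adjusted
excess burden* of VTE: for each outcome Y (90-day readmission, outpatient
visit with problem, each payment component, total payment, hospital days),

Δ = E[Y(VTE=1) − Y(VTE=0)]

over the matched case population. Because exposure is not randomised, the
pipeline combines propensity-score matching (design stage) with regression
standardization (analysis stage).

## Cohort construction

- **Eligibility**: age ≥ 18, not pregnant, no contraindication to
  anticoagulant therapy. Criteria are logged independently, so overlapping
  exclusions are visible.
- **VTE classification** (ICD-10, day offsets counted from surgery day 0,
  window inclusive at day 90, both configurable):
  - PE: any I26.x
  - PTP: I80.1–I80.3 or I80.8
  - VET: any I82.x
  - DVT+PE: a deep-vein code (I80.1–I80.3, configurable) co-occurring with a
    PE code. The deep-vein set is the only defensible reading of the
    lower-extremity thrombophlebitis codes; I80.8 (other sites) is PTP only.
  - Precedence when groups co-occur: DVT+PE > PE > VET > PTP (severity
    ordering, configurable). Malformed codes are ignored with a warning.
- **Elixhauser flags**: the 30 chronic-condition indicators are set from a
  packaged, editable CSV of ICD-10 prefixes following the standard Quan et
  al. (2005) coding algorithm, with condition names aligned to the cohort's
  30 flags. Two deliberate edits: the pulmonary-circulation row excludes
  I26 (it would otherwise flag the exposure itself), and a few nonstandard
  condition splits ("liver failure", "aplastic anemia") are assigned the
  nearest Quan code blocks. Users with different coding practice can replace
  the table.
- **Costs**: five components (surgery, readmission, readmission drugs,
  outpatient visit, outpatient drugs), all ≥ 0; the 90-day total is their
  sum. Regional price differences are removed by dividing components by a
  user-supplied region wage index. A fixed exchange rate (US$1 = VND 23,255,
  2019) converts VND inputs at load time.

## Propensity matching

The exposure model is a probit of VTE on sex, age group (18–59 reference),
surgery type (neurosurgery reference), provider region (north reference) and
the 30 chronic flags; emergency admission is excluded by default but can be
included. Age enters only through age-group dummies (all continuous
matching variables are categorised). Scores are Φ(x'β̂).

Matching is greedy 1:1 nearest neighbor on the score, **without
replacement**, no caliper, cases processed in descending score order
(hardest-to-match first); distance ties go to the lowest control id, making
the result fully deterministic. All options (replacement, caliper, order)
are exposed. On small instances the greedy total distance is regression-
tested against the brute-force optimal assignment: greedy is never better
than optimal and coincides with it on well-separated score configurations.
Balance is reported as case %, control % and the standardized mean
difference SMD = (p̄₁−p̄₀)/√((s₁²+s₀²)/2) per covariate indicator, flagged at
|SMD| > 0.1 (the SMD column is an extension beyond simple percentage
contrasts; zero-variance covariates report SMD 0).

## Models

All three likelihood engines are fitted by Newton–Raphson with step-halving
(log-likelihood never decreases), convergence at max |score| < 1e-8 or
relative log-likelihood change < 1e-10, at most 100 iterations; covariance is
the inverse observed information (classical σ̂²(XᵀX)⁻¹ for OLS). Categorical
covariates use treatment coding against fixed reference levels so coefficient
vectors are byte-reproducible. Rank-deficient designs raise an error naming
the collinear columns; unobserved dummy levels are dropped before fitting.
Perfectly separated binary fits are reported with a warning and flagged
non-converged rather than silently truncated — matched cohorts with rare
conditions can separate. The matched-sample outcome models are unconditional
logistic regressions (conditioning on pair, i.e. conditional logistic, is not
implemented).

## Excess estimation

On the matched sample, models adjust for age group, sex, region and surgery
type, with VTE as either a single indicator (the "all VTE" row) or four
class dummies (PE, PTP, VET, DVT+PE against no VTE).

- **Event rates**: average marginal effect of toggling the exposure,
  (1/n) Σ [expit(x'β̂|v=1) − expit(x'β̂|v=0)].
- **Costs**: OLS on ln(cost); predictions retransformed to dollars with
  Duan's smearing factor φ = mean(exp(ε̂)), a nonparametric correction for
  the retransformation bias (φ ≥ 1 for intercept models by Jensen's
  inequality); the excess is the mean difference of the two counterfactual
  predictions. A single overall (homoscedastic) φ is used; when residual
  spread differs between arms this is an acknowledged approximation, and a
  group-specific variant can be obtained by fitting arms separately.
- **Component costs**: exactly zero when the triggering event is absent, so
  they cannot be logged directly; a two-part model (logistic any-cost ×
  log-linear cost-given-positive) is combined in the counterfactual
  prediction and reduces to the plain method when all costs are positive.
- **Hospital days**: identity-scale linear model, same recycled-prediction
  difference.
- **Uncertainty**: seeded nonparametric bootstrap over matched *pairs*
  (default 500 resamples; every model is refitted and re-smeared per
  resample). Resamples where a statistic is undefined (e.g. a class absent)
  are dropped from that cell's SE. The bootstrap was chosen because no
  analytic SE is available for the smeared counterfactual difference; a
  delta-method variant would be possible but is not implemented.
- **Cumulative cost curves**: per-arm cumulative mean cost by day, with the
  surgery payment at day 0 and readmission/outpatient components at their
  recorded event days; events dated outside the window are excluded with a
  warning. When nothing is excluded the day-90 gap equals the unadjusted
  difference in arm mean totals (tested to 1e-9).

## Synthetic cohort generator

The generator emulates the structure of a national surgical claims extract:

- Covariates drawn independently at the configured prevalences (defaults:
  the raw-sample prevalences of the study-population table — e.g. 40.17%
  female, 52.2% orthopedic surgery, 7.35% hypertension); age group, region
  and surgery type are mutually exclusive categories. An optional pregnancy
  (0.5% of women) and contraindication (0.3%) rate exercises the
  eligibility filter.
- VTE assigned Bernoulli(Φ(x'β)) with configurable probit coefficients whose
  default signs/sizes mirror the observed case–control contrasts (older age,
  female sex, vascular surgery, vascular/renal comorbidity enriched among
  cases); the default intercept (−3.5318) is calibrated by Monte Carlo so the
  marginal prevalence is ≈0.2%, matching the observed incidence scale.
  `calibrate_probit_intercept` recalibrates to any prevalence; estimation
  tests use 2% for power.
- VTE class drawn among PE/PTP/VET/DVT+PE (defaults 0.15/0.45/0.30/0.10 —
  deep-vein-dominated, as in claims practice); matching ICD-10 codes with a
  uniform day offset in [0, 90] are emitted, plus sparse non-VTE noise codes,
  so classification is exercised end to end.
- Cost components are log-normal **conditional on the triggering event**
  (exact zero otherwise), moment-matched to the published non-VTE
  means/SDs (e.g. surgery payment: log-mean 5.705, log-sd 1.055 ⇒ mean
  ≈ $524, SD ≈ $750); VTE multiplies every incurred component by a single
  factor (default 2, on the scale of the observed 2.25× total-cost ratio).
  Log-normality makes the log-linear cost model correctly specified, so
  recovery tests have closed-form truths.
- Outcomes are logistic with a VTE log-odds shift (defaults: readmission
  intercept −2.6 with VTE coefficient 1.8; outpatient −0.35 with 0.9 —
  baseline rates near 8% and 41%); hospital days are gamma (shape 2) with an
  additive VTE mean shift (default +1.9 days on a 7-day baseline).

Closed-form truth utilities (`analytic_outcome_ame`,
`analytic_excess_total_cost`) evaluate the generating model's exact
counterfactual contrasts over any covariate sample; they are generator-side
oracles, independent of the estimation path.

**What the generator does not emulate** — and hence what passing tests do
not establish about real claims data: correlated comorbidities (an optional
copula was considered and left out; flags are independent by default),
covariate-dependent cost levels (costs depend on covariates only through
event probabilities and VTE), longitudinal multi-admission streams, coding
error/under-ascertainment of VTE, mortality, and realistic fee schedules.
Estimator performance under those violations is untested here.

## Problem sizes and numerical choices

Recovery and coverage suites use 20 seeded replicates of n = 50,000 episodes
at 2% prevalence with 200-resample bootstraps; the prevalence calibration
uses a 400,000-draw Monte Carlo; the smearing closed-form check uses 10⁶
normal residuals (tolerance 0.003 around exp(σ²/2) at σ = 0.5). All
randomness flows from explicit integer seeds through `numpy.random.
default_rng`; identical configuration and seed reproduce every output file
byte for byte.

## Known limitations

- Unconditional (not pair-conditional) logistic models on the matched
  sample.
- Single overall smearing factor (see above).
- Greedy matching is order-dependent by construction; the default
  descending-score order is a heuristic, not an optimality guarantee.
- No censoring or survival adjustment of costs, no mortality-inclusive
  burden, no societal-perspective costs.
- The published class-specific excess estimates from the source national
  database cannot be reproduced without that database; the package instead
  validates the printed summary-table arithmetic exactly and validates the
  estimators by parameter recovery on synthetic cohorts.
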