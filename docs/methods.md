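# Methods

## The estimation problem

The exposure is receipt of any parenteral nutrition (PN) on at least one
day of therapeutic hypothermia (TH; days 1–3, day 1 = day of birth). The
estimand for binary outcomes is the marginal rate difference (and odds
ratio) between exposed and unexposed infants in a matched population, and
the mean difference for continuous outcomes. Treatment assignment is
assumed strongly ignorable given the recorded background covariates:
matching can only remove confounding through what is measured, so residual
confounding by unmeasured "sickness" is an acknowledged limitation of the
design, not of the implementation.

## Synthetic cohort model

The generator emulates the structure of a national neonatal EHR extract
for cooled infants. Its defaults encode the study conditions and are not
tuning knobs:

* **Covariate marginals** — male 0.55; gestational age ~ N(39.4, 1.6²)
  weeks; birth weight ~ N(3385, 621²) g; caesarean 0.47; cord-pH band
  probabilities 0.444 / 0.233 / 0.323 (given recorded) with 29.5% missing;
  Apgar-5 bands 0–1/2–4/5–7/8–10 at 0.155/0.375/0.30/0.085 plus missing;
  smoking yes/no/missing 0.14/0.70/0.16; and so on (see
  `config.DEFAULT_MARGINALS`).
* **Severity factor** — one latent N(0,1) "illness severity" per infant.
  Clinical-condition covariates (Apgar, cord pH, resuscitation, day-1
  ventilation/inotropes, admission physiology) load on it through a
  one-factor Gaussian copula, which preserves each marginal exactly while
  inducing realistic cross-correlation. Setting all loadings to zero
  recovers independent covariates. A single factor was chosen over a full
  correlation matrix because it is the minimal structure that produces
  confounding by indication, which is the phenomenon the pipeline must
  remove; the loadings are configurable.
* **True propensity** — a logistic model on a fixed, documented encoding
  (`synthetic_cohort.true_design`): intercept −0.815 (calibrated once so
  the marginal exposure proportion is ≈ 24.5%), negative coefficients on
  severity markers (Apgar 0–1 −0.30, pH < 6.9 −0.25, inotropes −0.30,
  ventilation −0.20, chest compressions −0.20, birth-weight z −0.15),
  +0.15 for missing pH, +0.20 for maternal smoking, and +0.04 per calendar
  year — about +0.007/year on the probability scale, the observed secular
  trend. Exposure is a Bernoulli draw on this score, so it is independent
  of latent severity *given* the observed covariates; matching on the
  covariates is therefore sufficient for unbiasedness, which is what the
  bias-reduction tests exercise.
* **Outcomes** — binary outcomes follow a linear-probability model
  `clip(base + slope·severity + effect·exposed, 0, 1)`. Baselines come
  from the unexposed arm of the emulated population (culture-positive
  late-onset infection 0.3%, pragmatic infection 25.3%, pragmatic NEC
  1.4%, survival 89.5%, hypoglycaemia 19%, breastfeeding 47%); default
  true effects are the emulated study's matched estimates (survival
  +3.1 pp, culture-positive infection +0.6 pp, pragmatic infection
  +0.8 pp, NEC −0.3 pp, hypoglycaemia −2.1 pp, central line +0.9 days,
  length of stay +0.8 days, first maternal milk −0.25 days). Length of
  stay is log-normal (median ≈ 11 days, IQR ≈ 8–16) plus a severity shift.
* **Exact realisability** — daily records are constructed to realise the
  drawn outcome flags exactly: a qualifying ≥5-day antibiotic run starting
  after day 3 exists iff the pragmatic-infection flag is true; NEC cases
  are a subset of those runs with nil-by-mouth on every run day; no other
  ≥5-day run is ever emitted. Consequently the derived phenotypes equal
  ground truth with equality, which the tests assert. Two small
  consequences: planting an antibiotic run can extend a short stay to fit
  it (a minor perturbation of the length-of-stay margin), and the
  central-line *day-count* effect is defined among line-holders while line
  *placement* is also more common in the exposed arm (97.9% vs 92.3%), so
  the marginal mean difference in line days slightly exceeds the planted
  0.9.
* **Edge cases** — configurable fractions of infants with a blanked day-2
  cooling flag (default 5% of fully cooled survivors), deaths during
  cooling (25% of deaths), early cessation of cooling without death
  (1.5%), and unexposed infants with unrecorded PN fields on days 1–4 (3%)
  for the complete-nutrition sensitivity filter.
* **Growth reference** — weight SD scores use a small synthetic mean/SD
  table by sex and postmenstrual week (`growth.py`) so the
  weight↔SDS round trip is exactly invertible in tests; real weight
  standards are out of scope.

Identical configuration and seed produce byte-identical tables. What
passing tests on this generator do **not** show: robustness to model
misspecification (the fitted propensity model nests the true one),
non-additive or heterogeneous treatment effects, informative missingness,
or recording error in real EHR data.

## Phenotype rules

* Day-2 cooling imputation: set to cooled iff missing, days 1 and 3 both
  cooled, and no death on days 1–3. No other imputation anywhere.
  "Died during cooling" means death on days 1–3 throughout.
* Eligibility: gestation ≥ 36+0, birth year in the configured window
  (default 2010–2017), and 3 cooled days or death while cooled.
* Exposure: PN flag true on ≥ 1 day whose cooled flag is true; a missing
  PN flag never counts.
* Consecutive-antibiotic rules use *maximal* runs: a run "starting after
  day 3" must have its first day on day ≥ 4 (a course running from day 3
  does not qualify). Pragmatic NEC requires nil-by-mouth on **every** day
  of a ≥5-day run plus a recorded diagnosis — the strict conjunction
  reading of "antibiotics while nil by mouth".
* A blood culture counts toward the primary outcome only if it is a pure
  pathogen growth (the commensal/contaminant category never counts) on
  day ≥ 4, applied unconditionally on discharge timing.
* Length of stay = discharge or death day under the day-1 convention;
  hypoglycaemia is an episode-level flag (any recorded day), mirroring how
  such diagnoses attach to care episodes rather than days.

## Propensity model

Categorical covariates get an explicit `missing` level (reference = first
sorted level); continuous covariates use missing-indicator + zero fill; no
infant is dropped for covariate missingness. Interactions are config-driven
with an empty default — there is no defensible way to guess a particular
"selection of interactions", so none is imposed. The fit maximises the
ridge-penalised Bernoulli log-likelihood (penalty 1e-6 by default, never on
the intercept) via scikit-learn's lbfgs on internally standardised columns
(coefficients are back-transformed; the penalty therefore acts on the
standardised scale, a numerical choice that is irrelevant at the default
penalty). With ridge = 0 the fit is exact ML, so the mean fitted score
equals the observed exposure proportion. Standard errors come from the
inverse penalised Fisher information; the c-statistic (AUC, ties counted
half) is reported as an overlap diagnostic.

## Matching

* Strata: consecutive 2-year birth bands crossed with cord-pH bands.
  Missing pH is a fourth exact-match band by default (16 cells over an
  8-year window) because a matched cohort can only balance missingness
  exactly if it is matched exactly; a strict 12-group mode
  (`strict_12_groups`) instead drops missing-pH infants from matching.
* Deciles are computed within each stratum once (they are deterministic
  given the scores). Ranking is by score with stable input order; tied
  scores always share a group (so a degenerate all-tied stratum forms one
  group), and distinct scores give group sizes differing by at most one.
  Strata with fewer than 10 infants get fewer groups.
* Pairing within a (stratum, decile) cell is uniformly random without
  replacement until the minority arm is exhausted — random rather than
  nearest-neighbour because replicating the matching only has meaning if
  pairing is stochastic; exchangeability within a decile is the standard
  justification. Replication r uses seed `base_seed + r` (PCG64), so the
  whole procedure is reproducible and pair counts are identical across
  replications by the min-rule.
* Balance is reported as standardised mean differences
  (Δmean / pooled SD), post-match values averaged over replications; a
  zero pooled SD with equal means yields SMD 0.

## Variance combination

Per replication, arms are treated as independent samples (unpaired
formulas for the rate difference, log-odds ratio and pooled-variance mean
difference); a paired McNemar-style alternative is out of scope. Across
replications the combined variance is the multiple-imputation-style rule
`W + (1 + 1/m)B` — the concrete reading adopted for "combining within- and
between-replication SEs" — isolated in `combine_replications`. Exact
agreement across replications sets B = 0 identically. With m = 1, B is
undefined and the within-SE is used (logged). Normal rather than t
reference throughout (per-replication n is large); odds ratios are
combined on the log scale. Percentages are shown to 1 decimal place with
half-up rounding.

The a-priori power helper uses the pooled-variance normal-approximation
two-proportion formula (printed in its output metadata) and is checked
against a Monte-Carlo power simulation; alternative classical formulas
give slightly different n, so no single published pair count is asserted.

## Disclosure control

Rendered counts of 1–4 appear as `<5`; the companion percentage is the
largest value a masked count could represent, rounded up to 1 dp (`<0.5`
at a denominator of 1240). Zero is not a disclosure risk and is shown.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 2 000–20 000 infants, 5–25
matching replications, and 50 repeats for the null-coverage property —
sizes chosen to make Monte-Carlo bounds (3 SEs; coverage ≥ 90%) sharp for
a desk-scale run. The acceptance script runs the full default pipeline at
n = 6030 with m = 25. Degenerate inputs are defined rather than fatal:
empty cohorts yield empty tables, an empty design matrix yields the
intercept-only fit, cells with an empty arm yield zero pairs, and an
all-tied score vector yields a single decile.

## Known limitations

* Propensity and outcome models in the generator share the covariate set;
  the pipeline's behaviour under misspecification is untested.
* The unpaired within-replication SE ignores the (slightly positive)
  outcome correlation within matched pairs and is therefore mildly
  conservative.
* Severe NEC is a passthrough flag with no daily-record substrate.
* Region is a synthetic three-level label used only by the
  years/region sensitivity filter; no real geography is modelled.
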