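# coolmatch

A tested, reproducible pipeline for the population-level question: **is
parenteral nutrition (PN) given during therapeutic hypothermia (TH)
associated with late-onset infection and other neonatal outcomes?**

Term and near-term babies with hypoxic-ischaemic encephalopathy receive
72-hour whole-body cooling. Roughly one in four also receives intravenous
(parenteral) nutrition during those three days, despite trial evidence in
critically ill children that early PN can be harmful. Because blood-stream
infection is rare in this population, a randomised trial would be
infeasible, so the question is studied observationally on routinely
recorded neonatal EHR data — which raises confounding by indication:
sicker babies may be both less likely to be started on PN and more likely
to die.

`coolmatch` implements the full analysis as a reusable library for
epidemiologists and biostatisticians:

* **Synthetic cohort generator** — infant-level and daily (one row per
  infant-day) tables emulating a national neonatal database extract, with a
  *known* true propensity model, known true treatment effects, realistic
  missingness (e.g. ~29% missing cord pH) and the edge cases the cleaning
  rules target. Every downstream stage is testable without any restricted
  data.
* **Phenotype derivation** — eligibility (gestation ≥ 36+0 weeks, 3 days of
  cooling or death during cooling), the day-2 cooling imputation rule,
  exposure (any PN on a cooled day), and all outcomes: culture-positive
  late-onset infection (pathogen growth after day 3), pragmatic infection
  (≥ 5 consecutive antibiotic days starting after day 3), pragmatic NEC,
  survival, length of stay, hypoglycaemia, breastfeeding measures,
  central-line days, discharge weight SD score.
* **Propensity estimation** — ridge-stabilised logistic regression of
  exposure on all background covariates with explicit missing-category
  handling, `e(x) = P(PN = 1 | x) = logit⁻¹(x'β)`.
* **Replicated stratified matching** — exact strata (four 2-year birth
  bands × cord-pH bands >7.0 / 6.9–7.0 / <6.9 / missing), propensity score
  deciles *within* each stratum, then random 1:1 pairing per cell, repeated
  m = 25 times.
* **Estimation** — per-replication rate differences / odds ratios / mean
  differences, combined across replications with
  `SE² = W + (1 + 1/m)·B` (W = mean within-replication variance, B =
  between-replication variance of the estimates), normal 95% CIs and
  two-sided p-values; plus the exposure calendar-time trend and a
  two-proportion power calculation.
* **Reporting** — balance, outcome and effect tables with statistical
  disclosure control (counts 1–4 rendered as `<5`, e.g. `<5 (<0.5)`).

## Worked example

```python
from coolmatch import PipelineConfig, run_pipeline

run_pipeline(PipelineConfig(outdir="demo", n_infants=6030, seed=1,
                            m_replications=25))
```

This simulates 6030 cooled infants (the default configuration encodes the
study conditions: ~24.5% exposure with a small upward calendar trend, and
true effects such as +3.1 percentage points on survival), derives the
analysis table, fits the propensity model, runs 25 matching replications
and writes `report.md`, whose header for seed 1 reads:

```
Eligible infants: 5907; exposed (parenteral nutrition during cooling): 1477 (25.0%).
Exposure trend: slope 0.0101/year (p=3.65e-05).
Matched pairs per replication: 1460 (25 replications).
```

and whose effect table (`effects_table.csv`) includes:

```
survived,rate_difference_pp,3.5 (1.1 to 5.8),0.004
survived,odds_ratio,1.59 (1.17 to 2.16),0.003
pragmatic_loi,rate_difference_pp,2.4 (-1.1 to 5.9),0.180
```

i.e. the matched analysis recovers the planted +3.1-point survival
difference (3.5 ± 1.2 here) after removing the planted
confounding-by-indication, and the disclosure rule masks any matched cell
with 1–4 events. The same stages are available as a CLI
(`coolmatch simulate | derive | propensity | match | estimate | run`).

## Layout

```
src/coolmatch/
  config.py            # SimulationConfig / PipelineConfig (+ YAML loading)
  synthetic_cohort.py  # generator with ground truth
  growth.py            # synthetic weight-for-age reference (SDS round-trip)
  phenotype.py         # eligibility, imputation, exposure, outcomes
  propensity.py        # design matrix + penalised logistic fit
  matching.py          # strata, deciles, replicated random 1:1 pairing
  estimation.py        # effect estimators, variance combination, trend, power
  report.py            # tables, suppression, pipeline driver
  cli.py               # click CLI
docs/methods.md        # model, assumptions, parameter choices, limitations
```
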