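# Methods

## The problem this package addresses

In non-randomised drug-safety and drug-effectiveness studies built on
routinely collected health records, the treated and comparator groups
differ in ways that are hard to measure directly — disease severity,
frailty, overall contact with the health system. High-dimensional
propensity scores (HDPS) treat the thousands of diagnosis, prescription and
hospitalisation codes in the record as *proxies* for those constructs:
candidate binary covariates are generated mechanically from the coding
stream, ranked by their potential to confound, and the top-ranked ones are
added to an investigator-specified ("prespecified") propensity-score model.

The package implements that workflow end to end for an active-comparator
cohort with a binary exposure and rare time-to-event outcomes over a short
fixed window, together with a synthetic EHR generator whose confounding
structure is known, so every stage can be validated without access to any
real (and typically non-shareable) patient-level data.

## Pipeline

1. **Code mapping** (`code_mapping`). Raw observation codes are mapped to
   ICD-like codes and truncated to the 3-character clinical category;
   hospitalisation codes are truncated directly; prescription codes are
   mapped to 6-character BNF-paragraph-like classes, with a fallback table
   (first six characters of a chapter string) for codes missing from the
   primary table and a manual-override hook that takes precedence over
   both. Unmapped events are dropped and reported as a (code, count) table.
   Codes that define the exposure arms (the bronchodilator and inhaled
   corticosteroid classes) and the outcome (the COVID-19 diagnosis class)
   are excluded from the covariate pool; codes behind the prespecified
   covariates are deliberately *not* excluded.
2. **Recurrence covariates** (`covariates`). Events are restricted to a
   12-month assessment window before the index date (days 1–365). For each
   (dimension, code), per-patient occurrence counts yield up to three
   nested indicators — once (≥ 1), sporadic (≥ median of positive counts),
   frequent (≥ 75th percentile) — with thresholds computed among patients
   having at least one occurrence and ties qualifying. For primary-care
   observations the `once` indicator is redefined as *ever recorded before
   index*, since chronic conditions are not re-coded at every visit. No
   marginal-prevalence filter is applied: rare codes stay in the pool and
   the prioritisation step judges them. Indicator columns that are
   identical within a code collapse to the lowest level, so the propensity
   model never receives exact duplicates.
3. **Bross prioritisation** (`prioritisation`). Each candidate covariate C
   is scored by the bias multiplier
   `[P_C1 (RR_CD − 1) + 1] / [P_C0 (RR_CD − 1) + 1]`, where P_C1/P_C0 are
   its prevalences among exposed/unexposed and RR_CD its outcome relative
   risk; RR_CD < 1 is inverted so harmful and protective associations rank
   symmetrically, and candidates are ordered by |log bias| (ties broken on
   the covariate id for reproducibility). Covariates that behave like
   instruments — |log RR_CE| > 1.1 and |log RR_CD| < 0.5 — are flagged and
   removed before ranking, because adjusting for strong exposure-only
   predictors amplifies residual bias. RR_CD is estimated in the unexposed
   stratum by default (full-cohort estimation is a config option), and a
   2×2 table with any zero cell gets 0.1 added to every cell so
   rare-outcome covariates remain scoreable. Scores are outcome-specific:
   the ranking is recomputed per outcome and per cohort definition.
4. **Propensity model, weights, trimming, balance** (`weighting`). Plain
   logistic regression of exposure on prespecified + top-k empirical
   covariates (k = 0 is the conventional analysis); collinear columns are
   dropped with a warning and perfect separation raises with the offending
   columns named. Stabilized ATE weights are p_E/PS for the exposed and
   (1 − p_E)/(1 − PS) otherwise. Scores are trimmed to the common-support
   interval [max of arm-wise PS minima, min of arm-wise maxima], bounds
   inclusive, each analysis trimming on its own PS. Balance is summarised
   as absolute standardized mean differences with pooled-variance
   denominator √((v₁+v₀)/2); variances use the frequency-weight form with
   the weighted mean; categorical covariates use the Yang–Dalton
   Mahalanobis statistic over the K−1 level proportions so each categorical
   covariate yields a single SMD. No weight truncation is applied; instead
   the max weight and per-arm effective sample size (Σw)²/Σw² are reported,
   because extreme weights, not their hidden repair, are the diagnostic of
   interest.
5. **Outcome models** (`outcomes`). Exposure effects on the weighted,
   trimmed cohort: Cox hazard ratios (Efron tie handling — event times are
   day-resolution and tie often — and a robust sandwich variance, since
   model-based variances are dishonest under estimated weights), logistic
   odds ratios (robust variance), risk differences from Hajek-weighted
   risk means with an influence-function standard error (stratified
   bootstrap optional), weighted Kaplan–Meier curves, and a scaled-
   Schoenfeld-residual check of proportional hazards that is reported but
   never alters an estimate. Wald 95% intervals are formed on the log
   scale for ratio estimands.
6. **Sensitivity machinery** (`sensitivity`). Missing-data rules (missing
   BMI → "normal"; missing ethnicity → its own "Unknown" level; missing
   IMD → row dropped and counted; any other missingness is an error); the
   k-grid sweep (default 100/250/500/750/1000); and a one-by-one
   trajectory in which the top-ranked covariates are added one at a time
   with the ranking frozen and the propensity model refitted from scratch
   at each step, recording the estimate alongside the max weight and
   effective sample sizes so that single influential covariates are
   visible as jumps.

## The synthetic EHR generator

`synthetic` emulates a COPD-like active-comparator cohort observed over a
184-day window (the length of a pandemic first wave), with ~40% receiving
the exposure drug class:

* **Prespecified covariates** are independent binaries and categoricals
  with prevalences loosely matching a UK COPD population (past asthma 17%,
  COPD exacerbations in the past year 38%, flu vaccination 79%, five-level
  deprivation index, four-level BMI, …). Some shift treatment choice
  (past asthma strongly, prior exacerbations, vaccinations), some shift
  the outcome hazard (age, sex, cardiovascular disease, kidney disease,
  immunosuppression), so the conventional propensity score has real
  confounding to remove. BMI, ethnicity and deprivation values are set to
  missing at the rates the missing-data rules expect (0.7%, 9.9%, 0.05%).
* **Latent severity and frailty** are standard-normal constructs withheld
  from every estimation table. By default one latent SD multiplies the
  exposure odds by e^0.5 ≈ 1.65 (severity) / e^0.3 (frailty) and the
  outcome hazard by e^0.5. These defaults were calibrated so that the
  conventional analysis of a null exposure effect is biased by about
  +0.35 on the log-HR scale (an apparent HR ≈ 1.4) — the magnitude of the
  conventional-vs-HDPS displacement reported in published applications of
  this design — rather than an implausibly extreme regime in which the
  weighting estimator itself becomes unstable.
* **Proxy codes.** Each dimension carries a bank of confounder codes; code
  j for latent L fires with probability expit(4 · (L − t_j)), with the
  thresholds t_j spread over (−1.5, 2.0) *jointly across the three
  dimensions*, so the indicators form a staircase of roughly a dozen
  distinct cut points per latent covering the range where the exposure
  odds and the outcome hazard actually vary (a grid stopping short of the
  extreme tail keeps every proxy's prevalence above ~2%, so its
  outcome association remains estimable at a 1% event rate). A logistic
  propensity model on such a staircase reconstructs the latent closely;
  with these defaults the residual confounding left by discretization is
  about +0.02 on the log-HR scale against a true-propensity benchmark.
  Per-patient occurrence counts are
  1 + Binomial(9, q) with q increasing in the latent, so the sporadic and
  frequent recurrence levels carry additional signal. Event dates are
  uniform over the last year (two years for observations, so the
  ever-present redefinition has work to do).
* **Instrument-like codes** occur with prevalence 0.30 among the unexposed
  and 3.2× that among the exposed — by construction exposure-associated
  only, with a generator-defined prevalence ratio above the e^1.1 cutoff.
  They are deliberately *common* codes: with a ~1% outcome, the
  covariate–outcome relative risk of a rare code is estimated from
  single-digit event cells and no instrument-exclusion rule could behave
  reproducibly.
* **Noise codes** fire independently of everything, with prevalences
  spread over 0.05–0.30.
* **Outcome.** Exponential survival with a log-linear hazard,
  administrative censoring at day 184 plus ~2% independent random
  censoring; the baseline hazard gives ≈ 1% cumulative risk; times are
  rounded up to whole days (hence ties, hence Efron). The conditional
  exposure effect defaults to null and is configurable, so the generator
  provides a known estimand for recovery tests.
* **Treatment-drug codes** (the regimen the arms are defined by) are
  emitted into the prescription stream for every patient and must be
  removed by the code-exclusion step — an end-to-end check that exclusion
  actually happens.
* **Mapping tables** map two raw variants to each harmonized concept
  (many-to-one), route a share of prescription variants through the
  fallback chapter table, and withhold an exact `fraction_unmapped` share
  of variants (default 5%) to exercise the unmapped-report path.

What the generator does *not* emulate: realistic code vocabularies,
calendar-time structure (dates are "days before index" integers),
treatment-episode dynamics or discontinuation, competing risks,
within-patient correlation of distinct codes beyond what the shared
latents induce, and outcome-dependent observation processes. Passing tests
therefore demonstrate that the machinery is correct and that the method
behaves as published *under its own assumptions* — not that HDPS removes
confounding in any particular real dataset.

## Numerical and design choices

* **Quantile convention** for recurrence thresholds: interpolating
  ("linear", R's default) by default — e.g. positive counts {1, 2, 4, 8}
  give median 3 and 75th percentile 5 — with a nearest-rank (⌈qm⌉-th
  smallest) alternative exposed as `AnalysisConfig.quantile_rule`.
* **Propensity fitting**: Newton iterations with tolerance 1e-10 (falling
  back to L-BFGS when the Hessian is singular); fitted probabilities at
  machine-0/1 are treated as separation and rejected rather than silently
  clipped.
* **Weighted Cox**: Newton precision 1e-12 so the estimate matches an
  independent maximiser of the weighted partial likelihood to ~1e-9.
* **Stabilized weights** use the marginal exposure prevalence of the
  analysis cohort; trimming happens after weight computation, and the trim
  is applied once (re-trimming an already-trimmed cohort can in principle
  move a bound when the new arm-wise minimum rises — with bounds attained
  in both arms the operation is exactly idempotent).
* **Zero cells** in any covariate 2×2 get +0.1 per cell (both the
  covariate–outcome and covariate–exposure tables), keeping rare
  covariates scoreable with finite relative risks.
* **Ties** in |log bias| are broken lexicographically on the covariate id;
  covariate ids are deterministic `dimension:code:level` strings.
* **Degenerate inputs**: a code with zero positive in-window counts emits
  no covariates (unless ever-present in the observation dimension, which
  emits the redefined `once` only); an exposure arm with zero events makes
  the HR inestimable and raises; a single event makes the proportional-
  hazards check return an `insufficient_events` flag instead of a number.

## Problem sizes used in the checks

The simulation studies in the test suite and the acceptance script use
n = 20 000 patients per replicate with 8 confounder, 2 instrument and 20
noise codes per dimension (≈ 280 candidate covariates), k = 100 empirical
covariates, 50 replicates in the test suite and 20 in the acceptance
script; structural tests use cohorts of 1 000–3 000. These sizes give
Monte-Carlo standard errors a few times smaller than the effects being
checked while keeping a full run of the suite in the minutes range.

## Known limitations

* The Bross score handles binary covariates, exposures and outcomes only;
  follow-up time is ignored at the ranking stage (the outcome models use
  it). With ~1% outcomes the covariate–outcome relative risks that drive
  both the ranking and the instrument flags are noisy; instrument flagging
  is reliable for common codes and intrinsically unreliable for rare ones.
* Outcome-dependent covariate selection plus inverse-probability weighting
  is volatile in finite samples when outcomes are rare: single patients
  with rare covariate combinations, large weights and an event can move
  the estimate visibly. The one-by-one trajectory and the max-weight/ESS
  diagnostics exist precisely to surface this; nothing in the pipeline
  hides it.
* Multiple imputation of missing ethnicity is out of scope; the supported
  path is the "Unknown" category rule.
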