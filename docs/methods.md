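# Methods

## Overview

`fertiopt` estimates, per oocyte-retrieval cycle, how many of the retrieved
oocytes should be exposed to sperm so that one live birth is achievable
without a large surplus of cryopreserved embryos. Three models are fitted
to registry-style data and combined by a deterministic rule; because the
registry data the method targets is access-restricted, the package also
ships a synthetic-registry generator with retained ground truth so that
every stage can be validated end to end.

## Shared covariates and coding

All three models use the same covariate set: female age group (`<32`,
`32-34`, `35-37`, `38-40`, `41-42`, `>42`), clinic region, AMH band
(`unknown`, `<1`, `1-<4`, `>=4` ng/mL), diminished-ovarian-reserve (DOR)
diagnosis, and number of oocytes retrieved (linear term). Categorical
covariates are reference-coded against the youngest age group, the first
region in sorted order, and the `unknown` AMH band; AMH missingness is a
first-class category, never imputed. Levels are frozen at fit time;
prediction at an unseen level raises an error rather than extrapolating.

## Model 1 — day of transfer

A maximum-likelihood logistic regression of the day-5 indicator (transfer
or freeze on day 5 or later, versus day 2–4). A cycle whose predicted
day-5 probability falls below the threshold τ = 0.75 is classified as a
poor-prognosis day-3 cycle for which all retrieved oocytes are exposed to
sperm. A tie (`p == τ`) classifies day 5.

## Model 2 — usable-blastocyst yield

The outcome is the count of usable blastocysts — those transferred from
the cycle plus those frozen — out of the retrieved-oocyte denominator,
among day-5 cycles. Real yield distributions are wider than binomial
sampling allows, so the default family is quasi-binomial: binomial mean
structure with heteroscedasticity-robust (HC1 sandwich) standard errors.
A sandwich covariance was chosen over the classical constant
Pearson-scale quasi-likelihood correction because the overdispersion in
blastocyst counts is cycle-level (beta-binomial-like): its variance
inflation grows with the number of oocytes, which a single scale factor
misstates. The Pearson X²/df is still reported as a `dispersion`
diagnostic (≈ 1 under pure binomial sampling).

## Model 3 — blastocysts transferred until the first live birth

Per patient, day-5 transfers are walked in treatment order, accumulating
blastocysts transferred until the first live birth; records ending without
a live birth are right-censored at the accumulated count. A parametric
accelerated failure time model treats this count as a positive "time".
Three families are supported — Weibull, log-normal, log-logistic — and by
default the family is chosen by lowest AIC on the training data (on
default synthetic cohorts the log-normal wins). The per-patient prediction
is the closed-form median of the fitted distribution; the closed forms are
cross-checked in the test suite against numerical inversion of the
survival function.

## The recommendation rule

For a predicted day-5 cycle, with `B` the predicted median blastocyst need
and `p` the predicted yield proportion,

```
N = ceil( (B / p) * m * k ),   m = 0.70 if ICSI else 1.0
```

capped at the number of oocytes retrieved (`k` = desired children,
default 1). The ICSI factor reflects that only mature (metaphase-II)
oocytes, about 70 % of those retrieved, are injected. Every
recommendation carries a reason code: `predicted_day3`,
`ratio_ge_retrieved`, or `ratio_lt_retrieved`; only the last spares
oocytes from fertilization.

## The synthetic registry

The generator simulates patients and cycles in the style of a national ART
outcome registry:

* **Covariates.** Age strata drawn from fixed probabilities; a generic
  categorical region (default 8 levels) with mean-zero Gaussian effects on
  each linear predictor; AMH log-normal with an age-dependent location and
  35 % missingness; DOR from a logistic model on age and AMH band; ICSI,
  donor-oocyte, gestational-carrier and PGT flags as independent coins;
  cycle years uniform over 2014–2019.
* **Oocytes.** A truncated negative-binomial count whose log-mean falls
  with age and DOR and rises with AMH.
* **Cycle fate.** An independent "cancellation" coin (probability falling
  with oocyte count) labels roughly one cycle in five `none` — no
  transfer-or-freeze day is recorded, mirroring registries where a
  substantial minority of started cycles never reach a labelled embryo
  outcome. Among the rest, a day-5 versus day-3 label is drawn from a
  logistic model (the ground-truth β*). Because the cancellation coin is
  independent of the day-5 latent given the covariates, the day-5 logistic
  remains exactly recoverable from the labelled cycles.
* **Blastocysts.** For day-5 cycles, a beta-binomial count over the
  retrieved oocytes (ground-truth γ* on the logit mean, intra-cycle
  correlation ρ = 0.06).
* **Transfers and births.** One or two blastocysts per transfer (two more
  likely at older ages; day-3 transfers use up to three cleavage embryos);
  live birth is Bernoulli with age-specific probabilities; after each
  failed transfer a patient drops out with probability 0.15 (the censoring
  mechanism); patients without a birth may start one further stimulation
  cycle (probability 0.55).

Randomness uses a named-substream design: every variable, cycle and
transfer round draws from its own `SeedSequence(seed, spawn_key=...)`
stream, so the first *n* patients of a cohort are identical whatever the
cohort size, and all columns are reproducible elementwise.

### Calibration

The default parameter values were fixed once, before the test suite was
frozen, so that the simulated marginals sit at values a clinician would
recognize from published summaries of US national ART registry outcomes:
median 10 oocytes retrieved per cycle (IQR ≈ 6–17), conditional medians 13
(day-5 cycles) and 7 (day-3 cycles), a day-5 share declining from ≈ 85 %
in the youngest stratum to ≈ 42 % in the oldest, live-birth fractions of
≈ 43 % per day-5 transfer and ≈ 24 % per day-3 transfer, and a median
usable-blastocyst yield of ≈ 0.29 (IQR ≈ 0.18–0.43). The calibrated
defaults are the study conditions of this package; they are not adjusted
to make tests pass, and the acceptance checks verify them at n = 100 000
within Monte-Carlo tolerance.

## Evaluation conventions

* Medians and IQRs use linear-interpolation quantiles (the convention is
  a fixed, documented choice).
* Percentages are reported to one decimal.
* Age-group summaries report, per stratum, the share of cycles recommended
  to expose all versus fewer than all oocytes, the median (IQR)
  recommendation among the "fewer" cycles, and the total oocytes spared.
* A published 6×2 grid of recommendation counts by age group ships with
  the package; its derived percentages (66.2 % "fewer" under age 38,
  47.8 % overall) are recomputed exactly from the counts.

## Design decisions

* Fitting is delegated to established engines — statsmodels GLM for
  models 1–2, lifelines AFT fitters for model 3 — while the scientific
  logic (design coding, thresholding, median closed forms, the
  recommendation rule, the generator) is implemented in-package.
* The train/test split is patient-level, equal-sized, with a split seed
  distinct from the simulation seed.
* The day-of-transfer threshold, maturity fraction and desired-children
  multiplier are explicit parameters everywhere, with defaults 0.75, 0.70
  and 1.

## Limitations

* All numerical validation is against the package's own synthetic
  generator; real-registry coefficients and savings will differ.
* The region covariate is a generic categorical stand-in, not actual US
  states; clinic-level clustering is not modelled.
* The AFT treats a discrete blastocyst count as continuous time; with
  typical counts of 1–12 this is an approximation, mitigated by reporting
  the median rather than the mean.
* Censoring (patient dropout) is assumed independent of prognosis given
  the covariates; informative dropout would bias model 3 and should be
  examined before any real-data use.
* Embryo-quality grading, infertility diagnosis and treatment-protocol
  covariates are out of scope; predictions condition only on the five
  shared covariates.
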