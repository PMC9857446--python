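# fertiopt

Estimate the optimal number of oocytes to attempt to fertilize in an
assisted-reproductive-technology (ART) treatment cycle.

## The problem

In a typical IVF cycle every retrieved oocyte is exposed to sperm, and the
resulting embryos that are not transferred are cryopreserved. Patients with
a good prognosis routinely end up with more frozen embryos than they will
ever use, which creates long-term storage burdens and difficult disposition
decisions. The question this package answers, per cycle and before
fertilization, is: *given this patient's characteristics and the number of
oocytes just retrieved, how many of them should be exposed to sperm so that
one live birth is achievable without creating a large embryo surplus?*

## The model

Three models are fitted to registry-style cycle data and combined into a
single rule:

1. **Day of transfer** — a logistic regression of whether the cycle reaches
   a day-5 (blastocyst-stage) transfer rather than a day-3
   (cleavage-stage) transfer, on age group, clinic region, AMH band,
   diminished-ovarian-reserve (DOR) diagnosis and number of oocytes
   retrieved. Cycles with predicted day-5 probability below a threshold
   (default 0.75) are treated as poor-prognosis cycles for which **all**
   oocytes should be fertilized.
2. **Blastocyst yield** — a quasi-binomial (overdispersed logistic) model
   of the proportion of retrieved oocytes that become usable blastocysts
   (transferred + frozen), on the same covariates.
3. **Blastocysts needed for a live birth** — a right-censored accelerated
   failure time (AFT) model of the cumulative number of blastocysts
   transferred across a patient's cycles until the first live birth;
   patients whose record ends without a live birth are censored. The
   prediction is the median of the fitted distribution (family chosen by
   AIC among Weibull, log-normal and log-logistic).

For a predicted day-5 cycle the recommended number of oocytes to expose to
sperm is

```
N = ceil( (B / p) * m * k )
```

where `B` is the predicted median blastocyst need (model 3), `p` the
predicted usable-blastocyst proportion (model 2), `m = 0.70` for ICSI
cycles (only mature oocytes are injected; 1.0 otherwise) and `k` the number
of desired children. `N` is capped at the number of oocytes retrieved.

Because the national registry data this method targets is
access-restricted, the package ships a calibrated synthetic registry
generator (`fertiopt.synthetic_registry`) that retains its ground-truth
parameters, so every stage — fitting, prediction, recommendation,
evaluation — is testable end to end against known truth.

## Worked example

With a predicted blastocyst need of 4, a predicted usable-blastocyst rate
of 40 %, conventional insemination and 15 oocytes retrieved, the rule
recommends fertilizing `ceil(4 / 0.40) = 10` oocytes:

```python
>>> from fertiopt import recommend
>>> recommend(p_day5=0.82, yield_p=0.40, B=4.0, icsi=False, n_retrieved=15)
Recommendation(predicted_day='day5', p_day5=0.82, yield_p=0.4, blastocysts_needed_B=4.0, raw_ratio=10.0, maturity_factor=1.0, desired_children=1, recommended_n=10, expose_all=False, reason='ratio_lt_retrieved')
```

## Command line

```
fertiopt run-all --out results/            # simulate -> prepare -> fit -> recommend -> evaluate
fertiopt simulate --n-patients 20000 --seed 7 --out sim/
fertiopt prepare  --registry-dir sim/ --out prep/
fertiopt fit      --prepared-dir prep/ --out models/
fertiopt recommend --models-dir models/ --age 33 --region R01 --amh 2.5 --oocytes 18
fertiopt evaluate --recommendations results/recommendations.csv \
                  --cycles results/retrievals.csv --out results/
```

`run-all` simulates a cohort (default 100 000 patients), applies the
eligibility rules (first stimulation cycle 2014–2019, ≥ 1 oocyte retrieved,
no donor oocytes, gestational carriers or preimplantation genetic testing),
splits patients into equal train/test arms, fits the three models on the
training arm, and writes per-cycle recommendations and age-group summaries
for the test arm.

## Layout

```
src/fertiopt/
  core_registry.py                  registry schema, validation, CSV I/O
  synthetic_registry.py             calibrated cohort generator + ground truth
  cohort_prep.py                    eligibility, splitting, model tables
  design.py                         shared reference-coded design matrices
  day_of_transfer_model.py          model 1 (logistic + threshold)
  blastocyst_yield_model.py         model 2 (quasi-binomial yield)
  blastocysts_for_livebirth_model.py model 3 (censored AFT)
  recommendation_engine.py          the ceiling-of-ratio rule
  evaluation.py                     age-group summaries, oocytes saved
  cli.py                            command-line pipeline
docs/methods.md                     generative model, calibration, design choices
docs/column_dictionary.md           registry column reference
```

See `docs/methods.md` for the generative model behind the simulator, the
provenance of its calibration, and known limitations.
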