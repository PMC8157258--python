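# miscohort

Miscarriage ascertainment and incidence analysis for primary-care EHR
pregnancy cohorts, with a synthetic-cohort generator for end-to-end testing.

## The problem

Estimating the frequency and timing of miscarriage from routinely collected
primary-care records is hard: the start of pregnancy (the last menstrual
period, LMP) is often unrecorded, and loss events are coded under a mixture
of codes — some clearly miscarriage, some clearly termination of pregnancy
(TOP), many ambiguous. `miscohort` implements, as a reusable and tested
pipeline, the algorithmic core of a validation-study design for this
problem:

1. **Pregnancy episodes.** One episode per woman (her first pregnancy in
   the study window). Gestational age is `end_date − lmp_date` in whole
   days. When the LMP is recorded, plausibility filters keep gestational
   ages in [155, 320] days for delivery/stillbirth and [28, 154] days for
   loss/ectopic; when it is missing, the LMP is imputed by subtracting 280
   days (delivery/stillbirth), 74 days (loss) or 52 days (ectopic) from the
   end date.
2. **PPV-gated case validation.** Loss codes map to a taxonomy of three
   categories (miscarriage-suggestive, TOP-suggestive, unspecified) with
   ten subcategories. A random sample of each subcategory is checked
   against gold labels; subcategories whose positive predictive value (PPV)
   for miscarriage is below 85% are excluded from the confirmed-miscarriage
   pool. PPV intervals are exact (Clopper–Pearson).
3. **Survival analysis.** Follow-up runs from the LMP to the first of loss,
   gestational day 154 (week 22) or death. The package computes incidence
   rates per 1000 person-weeks with exact Poisson intervals, Kaplan–Meier
   curves with Greenwood variance, log-rank tests, the weekly event
   histogram, and adjusted hazard ratios from a Cox proportional-hazards
   model (Newton–Raphson on the partial likelihood, Efron ties), fitted one
   exposure at a time with the fixed adjustment set {age band, PCP-visit
   band, year of LMP}.

Because no patient-level data can be distributed, the package ships a
synthetic EHR generator (`miscohort.synthetic_ehr`) that emulates the study
conditions — ~65% recorded LMP, outcome mix 77.5/21.5/0.8/0.2, subcategory
confusion calibrated to the published chart-review PPVs, and an age-band
loss-hazard gradient of 1 / 1.21 / 1.76 / 3.34 — together with a truth
table acting as the gold standard for the simulated review.

## Worked example

```python
from miscohort import SimConfig, run_pipeline

manifest, out = run_pipeline(SimConfig(n_women=10_000, seed=1), "run1")
print(manifest["stage_rows"])
print(out["incidence_report"].head(7).to_string(index=False))
```

prints (abridged):

```
{'events': 23292, ..., 'cohort': 9999, 'losses': 2121, 'confirmed_pool': 1122}

       stratum  n_women  n_events  person_weeks  rate_per_1000pw  rate_ci_low  rate_ci_high  cumulative_incidence_pct
       overall     9999      1122      194390.4             5.77         5.44          6.12                      11.8
  lmp_recorded     6567       725      127776.4             5.67         5.27          6.10                      11.7
   lmp_imputed     3432       397       66614.0             5.96         5.39          6.58                      11.7
  age_band=<30     1961       159       39464.9             4.03         3.43          4.71                       8.5
age_band=30-34     2478       221       49176.0             4.49         3.92          5.13                       9.4
age_band=35-39     1682       227       31720.9             7.16         6.26          8.15                      14.4
 age_band=>=40      446       118        7414.7            15.91        13.17         19.06                      30.1
```

Of 10,000 simulated women, 2,121 had a coded pregnancy loss; after the
simulated review, the subcategories passing the 85% PPV gate contribute
1,122 confirmed miscarriages (11.8% cumulative incidence). Incidence grades
steeply with age, and the adjusted Cox model recovers the configured
gradient — on this run the ≥40-vs-<30 hazard ratio is 4.01 (95% CI
3.16–5.10), the true multiplier being 3.34:

```
 covariate level  n_event  pct_event  n_nonevent  pct_nonevent   hr  ci_low  ci_high
  age_band   <30      159       21.9        1802          30.8 1.00
  age_band 30-34      221       30.5        2257          38.6 1.12    0.91     1.37
  age_band 35-39      227       31.3        1455          24.9 1.78    1.45     2.18
  age_band  >=40      118       16.3         328           5.6 4.01    3.16     5.10
```

The same pipeline is exposed as a CLI (`miscohort simulate`, `build-cohort`,
`classify`, `analyze`, `cox`, `run-all`), each stage reading and writing
plain CSV.

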