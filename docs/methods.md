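# Methods

This note documents the models, parameter choices and numerical conventions
behind `miscohort`, and what the synthetic-data tests do and do not show
about real primary-care data.

## Synthetic cohort generator

The generator produces one pregnancy per woman aged 15–49, with calendar
dates drawn uniformly over a configurable study window (default
2002-01-01 – 2015-12-31, leaving room for a full-term pregnancy before the
window end). Age at the LMP is assigned once per woman and held fixed; the
birth date is back-computed so that completed years at LMP — defined
throughout the package as `floor((lmp − birth)/365.25)` — equals the drawn
age.

**Outcome model.** Ectopic pregnancy (0.8%) and stillbirth (0.2%) are drawn
first, independently of age. Every remaining woman passes through a
discrete-time survival process over gestational weeks 4–22: in week *w* she
suffers a pregnancy loss with probability

&nbsp;&nbsp;&nbsp;&nbsp;`p_w(m) = 1 − (1 − h_w)^(s·m)`

where `h_w` is the baseline weekly loss probability, `m` the hazard
multiplier of her age band (1 / 1.21 / 1.76 / 3.34 for <30, 30–34, 35–39,
≥40) and `s` a scale solved once per configuration (Brent bisection) so
that the population-average loss fraction equals the configured outcome mix
(21.5% at defaults). The power form makes the *continuous-time* hazards
exactly proportional across age bands with ratio `m`, so the Cox model
downstream estimates the configured multiplier without grouping bias; it
also means the baseline vector fixes only the *shape* of the hazard while
the outcome mix fixes its level. Women with no loss by week 22 complete the
pregnancy (gestational age ≈ N(280, 10²) days, clipped to [260, 300]).

The default `h_w` vector is calibrated so that, at the default age mix
(29.5 / 37.5 / 26.2 / 6.8%, the composition of the reference cohort),
weeks 7–12 carry ≈67% of losses and the median event week is 9. Event days
are uniform within the event week, capped at day 154 (week 22's only
admissible day, since follow-up ends there).

**Loss coding and confusion.** A loss event is recorded under a taxonomy
subcategory drawn from configurable frequencies (defaults proportional to
the published subcategory member counts), and its *true* outcome is then
drawn from the per-subcategory confusion mixture. The miscarriage share of
that mixture is exactly the subcategory's target chart-review PPV (1.00,
1.00, 0.90, 0.90 for subcategories 1.1–1.4; 0.55, 0.80, 0.75, 0.55 for
3.1–3.4; category-2 codes are genuinely terminations), so the expected
empirical PPV equals the configured value by construction. The
non-miscarriage remainder splits 70/30 between TOP and other losses — an
arbitrary but fixed split; only the miscarriage share matters downstream.

**Covariates and prescriptions.** Comorbidity flags and 90-day
pre-pregnancy prescriptions are drawn independently per woman with
prevalences of the magnitude seen in the reference cohort's baseline table
(e.g. anxiety 17.3%, hypothyroidism 6.5%, antibiotics 11.5%, folic acid
8.9%); benzodiazepines, antiepileptics and antihypertensives carry FDA
category D. PCP visit counts are negative-binomial (mean 5, shape 1.2) to
spread women across the four visit bands. Death during follow-up has
probability 0 by default (it is a censoring endpoint with no reported
frequency); it can be switched on per configuration.

Because covariates other than age are independent of the loss hazard, their
true hazard ratios are 1: the generator supports *null* calibration checks
and the age-gradient recovery, not effect-size recovery for comorbidities.

**What the generator does not emulate.** One pregnancy per woman (no
multi-pregnancy histories), no secular trends in age or prescribing, no
free-text descriptors beyond the taxonomy patterns, no regional/practice
clustering, no correlation between comorbidities, and prescription records
rather than actual drug intake. Passing tests therefore demonstrate that
the *pipeline arithmetic and estimators* are correct under the study's
structural assumptions — not that the study's real-data rates would be
reproduced from any particular EHR source.

## Episode construction

End-of-pregnancy events are ranked by date; same-day ties are broken by
taxonomy priority (loss categories 1 < 2 < 3, then ectopic, stillbirth,
delivery) and finally lexicographic code, making cohort construction
invariant to input row order. A recorded LMP is the latest LMP marker on or
before the end date. The plausibility filters apply only to the
recorded-LMP stream (imputed gestational ages are fixed by construction);
the retained windows are closed — [28, 154] for loss/ectopic, [155, 320]
for delivery/stillbirth — because the exclusion rules are stated as strict
inequalities. Episodes with end before LMP, or age at LMP outside 15–49,
are excluded with machine-readable reasons.

The 74- and 52-day imputation offsets are treated as fixed constants (they
are study-level medians); they are exposed for override in
`IMPUTATION_OFFSET_DAYS` but not re-estimated.

## Classification, review and the PPV gate

Codes are looked up in the taxonomy first; unknown codes fall back to
case-insensitive substring matching on the descriptor, longest pattern
first (so "spontaneous abortion" cannot be captured by the bare "abortion"
pattern), and anything unmatched lands in the catch-all subcategory 3.4.
The simulated review draws a simple random sample without replacement per
subcategory (censusing subcategories smaller than `review_n`, default 200)
and scores it against the truth table. The gate admits category-1 and
category-3 subcategories whose *point* PPV is ≥ 85% (intervals are
reported but not used for gating, matching the study's point-estimate
rule); category-2 subcategories are routed to a TOP pool regardless of
threshold. Keeping the rule general for category 3 — rather than
hard-coding its exclusion — lets alternative thresholds and confusion
settings be explored.

With finite review samples the gate is itself a random variable: a
subcategory with true PPV 0.90 fails a 85% gate with small probability
(≈0.8% at n=200). This is faithful to the design, not a defect.

## Survival analysis

Follow-up runs from day 0 (LMP) to the first of loss event, day 154, or
death. Competing losses (TOP, unspecified, ectopic) censor the
miscarriage-specific analyses at their exit day — the cause-specific
framing matching a single-event Kaplan–Meier analysis; no Aalen–Johansen
competing-risk estimator is attempted. Day-154 events count as events, not
censorings. Weeks are `floor(days/7)`.

* Incidence rates: events / Σ(exit_day/7) × 1000, with exact Poisson
  intervals by chi-square inversion.
* Kaplan–Meier: product-limit over distinct event times with Greenwood
  variance; cumulative incidence is 1 − S(154) with a log-scale Greenwood
  interval.
* Log-rank: k-sample statistic with hypergeometric variance, df = k − 1.

The two cumulative-incidence conventions (crude proportion vs KM
complement) agree exactly when nothing is censored before day 154 and are
both available; the incidence report uses the KM complement.

## Cox model

The partial likelihood is maximised by Newton–Raphson with step-halving;
ties are handled by the Efron correction (default; Breslow available).
Efron was chosen because weekly clustering of event days produces heavy
ties, for which Efron is markedly less biased. Convergence requires
max |score| < 1e-9 or relative log-likelihood change < 1e-10; standard
errors are from the inverse observed information. Coefficients diverging
beyond |β| > 15 are flagged as complete separation and no estimates are
reported. Banded covariates are dummy-coded against fixed references
(<30, 0–1 visits); year of LMP enters categorically by default (no trend
is assumed), switchable to linear.

The report fits one exposure at a time with the fixed adjustment set
{age band, visit band, lmp_year}, replicating the published table's
adjustment, rather than one saturated model. Drug exposures are flagged
from the half-open window [LMP−90, LMP) — closed at −90, open at the LMP —
and exposures with prevalence below 0.5% are listed but not fitted.

## Problem sizes and test design

The test suite checks exact arithmetic on the published inputs (gate
counts, table cells, imputation offsets, boundary enumeration), estimator
agreement with independent oracles (tail-probability inversion for the
exact intervals; hand product-limit and closed-form log-rank; brute-force
likelihood maximisation and a reference survival library for the Cox
fitter, to ≤1e-6), and stochastic recovery at simulation scale: the
age-band hazard-ratio recovery uses 20 replicates of n = 50,000 (the
fitted ≥40-vs-<30 CI covers 3.34 in ≥90% of replicates), rate-ratio and
week-share recovery use a single n = 50,000 cohort, and distributional
checks use exact binomial/chi-square tests at the 1% / 0.1% levels on
n = 10,000. These sizes give per-band event counts in the hundreds to
thousands, large enough that recovery tolerances (10% on rate ratios,
3 SE on shares) are dominated by real model error rather than noise.

## Known limitations

* Cause-specific censoring treats competing losses as independent given
  age; cumulative-incidence complements therefore slightly overstate the
  absolute risk relative to a competing-risk estimator.
* The Cox point estimate of the ≥40 multiplier shows mild (≈2–3%)
  attenuation from day-level grouping of the underlying weekly process;
  this is well inside the replicate CI width at n = 50,000.
* The imputed-LMP stream assigns every loss a 74-day gestational age by
  construction, so imputed-stream timing analyses are degenerate; timing
  outputs (KM, histogram, Cox) are restricted to the recorded-LMP stream.
* Descriptor matching is substring-based; it is a stand-in for real
  coding-dictionary work, not an NLP component.
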