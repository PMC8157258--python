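"""Published inputs from the validation study the pipeline is modelled on.

A large Spanish primary-care pregnancy cohort (2002–2015) identified 155,419
first pregnancies, classified every coded pregnancy loss into the
category/subcategory taxonomy, and estimated per-subcategory positive
predictive values (PPV) of miscarriage by manual chart review.  The printed
subcategory member counts and PPVs below are the inputs to the PPV gate and
to the worked examples; they are study outputs reproduced here as data, not
quantities this package estimates.
"""

from __future__ import annotations

#: women in each loss-code subcategory (flow-chart counts)
SUBCATEGORY_COUNTS: dict[str, int] = {
    "1.1": 16692,
    "1.2": 725,
    "1.3": 597,
    "1.4": 56,
    "2.1": 7255,
    "2.2": 259,
    "3.1": 7370,
    "3.2": 152,
    "3.3": 60,
    "3.4": 176,
}

#: chart-review PPV of miscarriage for category 1 and 3 subcategories;
#: for category 2 the reviewed outcome is TOP (confirmed at 100%)
SUBCATEGORY_PPVS: dict[str, float] = {
    "1.1": 1.00,
    "1.2": 1.00,
    "1.3": 0.90,
    "1.4": 0.90,
    "2.1": 1.00,
    "2.2": 1.00,
    "3.1": 0.55,
    "3.2": 0.80,
    "3.3": 0.75,
    "3.4": 0.55,
}

#: first-pregnancy cohort size and outcome composition
COHORT_TOTAL = 155_419
OUTCOME_COUNTS: dict[str, int] = {
    "completed": 120_469,
    "pregnancy_loss": 33_342,
    "ectopic": 1_285,
    "stillbirth": 323,
}
LMP_RECORDED_COUNT = 101_307

#: confirmed-miscarriage pool after the >=85% PPV gate
CONFIRMED_MISCARRIAGE_COUNT = 18_070

#: miscarriage / non-miscarriage column totals among women with recorded LMP
LMP_RECORDED_MISCARRIAGE_N = 7_827
LMP_RECORDED_REMAINING_N = 93_480
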