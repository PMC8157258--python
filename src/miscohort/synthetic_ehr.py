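"""Synthetic primary-care EHR generator for first-pregnancy cohorts.

Emulates the data structure of a primary-care pregnancy cohort: one
pregnancy per woman aged 15–49, coded end-of-pregnancy events, a recorded
last-menstrual-period (LMP) marker for ~65% of women, pre-pregnancy
comorbidity and prescription records, and a gold-standard truth table for
every simulated pregnancy (the stand-in for manual chart review).

Generative model
----------------
Ectopic pregnancy and stillbirth are drawn first with their configured
marginal probabilities.  Every remaining woman then passes through a
discrete-time survival process over gestational weeks 4–22: in week ``w``
she suffers a pregnancy loss with probability ``1 − (1 − h_w)^(s·m)`` where
``h_w`` is the baseline weekly loss probability, ``m`` the hazard
multiplier of her age band and ``s`` a scale solved once per configuration
so that the population-average loss fraction equals the configured outcome
mix.  Under this construction the underlying continuous-time hazards are
exactly proportional across age bands with ratio ``m``, which is what the
downstream Cox model estimates.  Women with no loss by week 22 complete
the pregnancy.

A loss event is recorded under a taxonomy subcategory drawn from the
configured subcategory frequencies, and its *true* outcome (miscarriage,
termination, or other) is drawn from the per-subcategory confusion
distribution — so the expected chart-review PPV of each subcategory equals
its configured value by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .taxonomy import (
    CodeTaxonomy,
    DELIVERY_CODE,
    ECTOPIC_CODE,
    LMP_CODE,
    STILLBIRTH_CODE,
    default_taxonomy,
)

__all__ = [
    "AGE_BANDS",
    "SimConfig",
    "ConfigError",
    "SamplingError",
    "generate_cohort",
    "write_dataset",
    "sample_event_day",
    "week_pmf",
    "expected_loss_probability",
]

AGE_BANDS = ("<30", "30-34", "35-39", ">=40")
_BAND_AGE_RANGES = {"<30": (15, 29), "30-34": (30, 34), "35-39": (35, 39), ">=40": (40, 49)}

#: gestational weeks over which the loss hazard is defined
HAZARD_WEEKS = tuple(range(4, 23))

#: baseline weekly loss probabilities (reference age band <30), weeks 4–22.
#: Calibrated so that, at the default age distribution and multipliers, the
#: population loss fraction is 21.5% and weeks 7–12 carry ~66% of losses.
DEFAULT_WEEKLY_HAZARD = (
    0.00367, 0.00659, 0.01096, 0.01675, 0.02180, 0.02323, 0.02180,
    0.01747, 0.01314, 0.00878, 0.00659, 0.00513, 0.00411, 0.00323,
    0.00264, 0.00220, 0.00176, 0.00147, 0.00117,
)

_DEFAULT_SUBCATEGORY_FREQS = {
    "1.1": 16692, "1.2": 725, "1.3": 597, "1.4": 56,
    "2.1": 7255, "2.2": 259,
    "3.1": 7370, "3.2": 152, "3.3": 60, "3.4": 176,
}

# true-outcome mixture per subcategory: the miscarriage share is the target
# chart-review PPV; the remainder splits 70/30 between TOP and other losses
# (category-2 codes are genuinely terminations).
def _confusion(ppv: float) -> dict[str, float]:
    return {"miscarriage": ppv, "top": 0.7 * (1 - ppv), "other": 0.3 * (1 - ppv)}


_DEFAULT_CONFUSION = {
    "1.1": _confusion(1.00),
    "1.2": _confusion(1.00),
    "1.3": _confusion(0.90),
    "1.4": _confusion(0.90),
    "2.1": {"miscarriage": 0.0, "top": 1.0, "other": 0.0},
    "2.2": {"miscarriage": 0.0, "top": 1.0, "other": 0.0},
    "3.1": _confusion(0.55),
    "3.2": _confusion(0.80),
    "3.3": _confusion(0.75),
    "3.4": _confusion(0.55),
}

_DEFAULT_COVARIATE_PREVALENCES = {
    "obesity": 0.070, "smoking": 0.077, "anemia": 0.004, "anxiety": 0.173,
    "asthma": 0.050, "depression": 0.078, "diabetes": 0.006,
    "epilepsy": 0.006, "hypercholesterolemia": 0.038, "hypertension": 0.010,
    "hypothyroidism": 0.065, "ibs": 0.018, "migraine": 0.062,
    "cardiopathy": 0.0002,
}

_DEFAULT_RX_PREVALENCES = {
    "antibiotics": 0.115, "acid_suppressants": 0.047, "benzodiazepines": 0.042,
    "antihypertensives": 0.006, "ssri": 0.017, "antimigraine": 0.006,
    "folic_acid": 0.089, "antiepileptics": 0.006, "thyroid_hormone": 0.019,
    "oral_corticosteroids": 0.025, "antihistamines": 0.045,
    "respiratory": 0.060, "codeine": 0.009,
}

#: FDA pregnancy risk category per drug class ("none" = not D/X)
_DEFAULT_RX_FDA = {
    "benzodiazepines": "D", "antiepileptics": "D", "antihypertensives": "D",
}


class ConfigError(ValueError):
    """A SimConfig field violates its invariants; the message names it."""


class SamplingError(RuntimeError):
    """Raised when an event day is requested under an all-zero hazard."""


def _check_probvec(name: str, probs: dict[str, float]) -> None:
    vals = np.asarray(list(probs.values()), dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {vals.sum():.12f}, not 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions the generator emulates: 65.2%
    of women with a recorded LMP, outcome mix 77.5 / 21.5 / 0.8 / 0.2
    (completed / loss / ectopic / stillbirth), subcategory frequencies and
    confusion calibrated to the published chart-review PPVs, an age-band
    hazard gradient of 1 / 1.21 / 1.76 / 3.34, and baseline comorbidity and
    prescription prevalences of the magnitude seen in the source cohort.
    """

    n_women: int = 10_000
    seed: int = 0
    age_distribution: dict[str, float] = field(
        default_factory=lambda: {"<30": 0.295, "30-34": 0.375, "35-39": 0.262, ">=40": 0.068}
    )
    p_lmp_recorded: float = 0.652
    outcome_mix: dict[str, float] = field(
        default_factory=lambda: {
            "completed": 0.775, "pregnancy_loss": 0.215, "ectopic": 0.008, "stillbirth": 0.002,
        }
    )
    subcategory_freqs: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(_DEFAULT_SUBCATEGORY_FREQS.values())
            for k, v in _DEFAULT_SUBCATEGORY_FREQS.items()
        }
    )
    code_confusion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CONFUSION.items()}
    )
    baseline_weekly_hazard: tuple[float, ...] = DEFAULT_WEEKLY_HAZARD
    age_hazard_multipliers: dict[str, float] = field(
        default_factory=lambda: {"<30": 1.0, "30-34": 1.21, "35-39": 1.76, ">=40": 3.34}
    )
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_PREVALENCES)
    )
    rx_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RX_PREVALENCES)
    )
    rx_fda_category: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_RX_FDA))
    visit_rate: float = 5.0
    p_death: float = 0.0
    study_start: str = "2002-01-01"
    study_end: str = "2015-12-31"
    review_n: int = 200

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ConfigError("n_women: must be a positive integer")
        _check_probvec("age_distribution", self.age_distribution)
        if set(self.age_distribution) != set(AGE_BANDS):
            raise ConfigError("age_distribution: bands must be " + ", ".join(AGE_BANDS))
        if not 0.0 <= self.p_lmp_recorded <= 1.0:
            raise ConfigError("p_lmp_recorded: must lie in [0, 1]")
        _check_probvec("outcome_mix", self.outcome_mix)
        if set(self.outcome_mix) != {"completed", "pregnancy_loss", "ectopic", "stillbirth"}:
            raise ConfigError("outcome_mix: keys must be completed/pregnancy_loss/ectopic/stillbirth")
        _check_probvec("subcategory_freqs", self.subcategory_freqs)
        for sub, mix in self.code_confusion.items():
            _check_probvec(f"code_confusion[{sub}]", mix)
        hz = np.asarray(self.baseline_weekly_hazard, dtype=float)
        if len(hz) != len(HAZARD_WEEKS):
            raise ConfigError(
                f"baseline_weekly_hazard: expected {len(HAZARD_WEEKS)} entries (weeks 4-22)"
            )
        if (hz < 0).any() or (hz > 1).any():
            raise ConfigError("baseline_weekly_hazard: entries must lie in [0, 1]")
        if abs(self.age_hazard_multipliers.get("<30", 0.0) - 1.0) > 1e-12:
            raise ConfigError("age_hazard_multipliers: reference band <30 must equal 1")
        for band, m in self.age_hazard_multipliers.items():
            if m <= 0:
                raise ConfigError(f"age_hazard_multipliers[{band}]: must be positive")
        if not 0.0 <= self.p_death <= 1.0:
            raise ConfigError("p_death: must lie in [0, 1]")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_weekly_hazard"] = list(self.baseline_weekly_hazard)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "baseline_weekly_hazard" in d:
            d["baseline_weekly_hazard"] = tuple(d["baseline_weekly_hazard"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived quantities ------------------------------------------------
    def hazard_scale(self) -> float:
        """Scale ``s`` applied to the cumulative weekly hazard so that the
        population-average loss probability matches the outcome mix."""
        p_other = self.outcome_mix["ectopic"] + self.outcome_mix["stillbirth"]
        target = self.outcome_mix["pregnancy_loss"] / (1.0 - p_other) if p_other < 1 else 0.0
        if target <= 0:
            return 0.0
        hz = np.asarray(self.baseline_weekly_hazard)
        if hz.sum() == 0:
            raise ConfigError("baseline_weekly_hazard: all-zero hazard with nonzero loss mix")
        pi = np.array([self.age_distribution[b] for b in AGE_BANDS])
        mult = np.array([self.age_hazard_multipliers[b] for b in AGE_BANDS])

        def mean_loss(s: float) -> float:
            p = 1.0 - (1.0 - hz[None, :]) ** (s * mult[:, None])
            return float(pi @ (1.0 - np.prod(1.0 - p, axis=1))) - target

        return float(brentq(mean_loss, 0.0, 1e4))


# ---------------------------------------------------------------------------
# event-day sampling

def week_pmf(hazard, multiplier: float = 1.0) -> np.ndarray:
    """Closed-form probability that a loss occurs in each of weeks 4–22,
    conditional on a loss occurring, under per-week probabilities
    ``1 − (1 − h_w)^multiplier``."""
    hz = np.asarray(hazard, dtype=float)
    p = 1.0 - (1.0 - hz) ** multiplier
    surv = np.concatenate([[1.0], np.cumprod(1.0 - p)[:-1]])
    f = p * surv
    tot = f.sum()
    if tot <= 0:
        raise SamplingError("all-zero hazard: no event week can be sampled")
    return f / tot


def sample_event_day(hazard, multiplier: float, rng: np.random.Generator) -> int:
    """Sample the gestational day of a pregnancy loss in [28, 154].

    Discrete-time survival sampling: the event week follows the
    hazard-implied conditional distribution over weeks 4–22, and the day is
    uniform within the week (clipped at day 154, the week-22 upper bound).
    """
    if multiplier <= 0:
        raise SamplingError("multiplier must be positive")
    pmf = week_pmf(hazard, multiplier)
    week = int(rng.choice(len(pmf), p=pmf)) + HAZARD_WEEKS[0]
    day = 7 * week + int(rng.integers(0, 7))
    return min(day, 154)


# ---------------------------------------------------------------------------
# cohort generation

def _sample_loss_days(pw_rows: np.ndarray, rng: np.random.Generator):
    """Per-row first-success week under row-specific weekly probabilities.

    Returns (has_event, day) where day is the gestational day for rows with
    an event (uniform within the event week, capped at 154).
    """
    u = rng.random(pw_rows.shape)
    hit = u < pw_rows
    has = hit.any(axis=1)
    week = hit.argmax(axis=1) + HAZARD_WEEKS[0]
    day = 7 * week + rng.integers(0, 7, size=len(week))
    return has, np.minimum(day, 154)


def generate_cohort(
    config: SimConfig,
    seed: int | None = None,
    taxonomy: CodeTaxonomy | None = None,
):
    """Simulate the cohort.

    Returns
    -------
    events, prescriptions, women, truth : pandas.DataFrame
        ``events`` holds coded clinical events (LMP markers, end-of-pregnancy
        outcomes, pre-LMP comorbidity records); ``prescriptions`` the 90-day
        pre-pregnancy drug records; ``women`` the registry (birth date, PCP
        visit count, death date); ``truth`` the gold-standard outcome and
        timing of every pregnancy.

    Identical ``(config, seed)`` yields identical output.
    """
    if config.n_women == 0:
        raise ConfigError("n_women: cohort must contain at least one woman")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    n = config.n_women

    start = np.datetime64(config.study_start, "D")
    end = np.datetime64(config.study_end, "D")
    window = int((end - start) / np.timedelta64(1, "D")) - 320
    if window <= 0:
        raise ConfigError("study_start/study_end: window shorter than one pregnancy")

    # demographics
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=[config.age_distribution[b] for b in AGE_BANDS])
    lo = np.array([_BAND_AGE_RANGES[b][0] for b in AGE_BANDS])[band_idx]
    hi = np.array([_BAND_AGE_RANGES[b][1] for b in AGE_BANDS])[band_idx]
    age = rng.integers(lo, hi + 1)
    lmp = start + rng.integers(0, window + 1, size=n).astype("timedelta64[D]")
    # birth date chosen so floor((lmp - birth)/365.25) == age
    back = np.ceil(age * 365.25).astype(int) + rng.integers(0, 364, size=n)
    birth = lmp - back.astype("timedelta64[D]")
    recorded = rng.random(n) < config.p_lmp_recorded
    visits = rng.negative_binomial(1.2, 1.2 / (1.2 + config.visit_rate), size=n)

    # outcomes: ectopic/stillbirth first, then the weekly loss process
    u = rng.random(n)
    p_ect = config.outcome_mix["ectopic"]
    p_sb = config.outcome_mix["stillbirth"]
    is_ect = u < p_ect
    is_sb = (~is_ect) & (u < p_ect + p_sb)
    scale = config.hazard_scale()
    mult = np.array([config.age_hazard_multipliers[b] for b in AGE_BANDS])[band_idx]
    hz = np.asarray(config.baseline_weekly_hazard)
    pw = 1.0 - (1.0 - hz[None, :]) ** (scale * mult[:, None])
    has_loss, loss_day = _sample_loss_days(pw, rng)
    is_loss = has_loss & ~is_ect & ~is_sb

    event_day = np.empty(n, dtype=int)
    event_day[is_ect] = rng.integers(35, 85, size=int(is_ect.sum()))
    event_day[is_sb] = rng.integers(155, 321, size=int(is_sb.sum()))
    event_day[is_loss] = loss_day[is_loss]
    is_completed = ~(is_ect | is_sb | is_loss)
    n_comp = int(is_completed.sum())
    event_day[is_completed] = np.clip(
        np.rint(rng.normal(280.0, 10.0, size=n_comp)).astype(int), 260, 300
    )

    # loss coding: subcategory then true outcome via the confusion mixture
    subcats = list(config.subcategory_freqs)
    sub_of_loss = np.array(subcats, dtype=object)[
        rng.choice(len(subcats), size=n, p=list(config.subcategory_freqs.values()))
    ]
    true_outcome = np.where(is_completed, "completed",
                   np.where(is_ect, "ectopic",
                   np.where(is_sb, "stillbirth", ""))).astype(object)
    u2 = rng.random(n)
    for sub in subcats:
        mix = config.code_confusion[sub]
        rows = is_loss & (sub_of_loss == sub)
        p_mc, p_top = mix["miscarriage"], mix["top"]
        true_outcome[rows & (u2 < p_mc)] = "miscarriage"
        true_outcome[rows & (u2 >= p_mc) & (u2 < p_mc + p_top)] = "top"
        true_outcome[rows & (u2 >= p_mc + p_top)] = "other"

    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if config.p_death > 0:
        dies = rng.random(n) < config.p_death
        death_date[dies] = (lmp + rng.integers(1, 155, size=n).astype("timedelta64[D]"))[dies]

    woman_id = np.arange(1, n + 1)
    end_date = lmp + event_day.astype("timedelta64[D]")

    # --- assemble events ---------------------------------------------------
    code_by_sub = {str(r.subcategory): (r.code, r.descriptor_pattern)
                   for r in tax.table.itertuples(index=False)}
    out_code = np.empty(n, dtype=object)
    out_desc = np.empty(n, dtype=object)
    out_code[is_completed], out_desc[is_completed] = DELIVERY_CODE, "delivery"
    out_code[is_sb], out_desc[is_sb] = STILLBIRTH_CODE, "stillbirth"
    out_code[is_ect], out_desc[is_ect] = ECTOPIC_CODE, "ectopic pregnancy"
    for sub, (code, desc) in code_by_sub.items():
        rows = is_loss & (sub_of_loss == sub)
        out_code[rows], out_desc[rows] = code, desc

    frames = [pd.DataFrame({
        "woman_id": woman_id, "date": end_date, "code": out_code, "descriptor": out_desc,
    })]
    if recorded.any():
        frames.append(pd.DataFrame({
            "woman_id": woman_id[recorded], "date": lmp[recorded],
            "code": LMP_CODE, "descriptor": "last menstrual period",
        }))
    for cond, prev in config.covariate_prevalences.items():
        has = rng.random(n) < prev
        if has.any():
            dates = lmp[has] - rng.integers(30, 1096, size=int(has.sum())).astype("timedelta64[D]")
            frames.append(pd.DataFrame({
                "woman_id": woman_id[has], "date": dates, "code": cond, "descriptor": cond,
            }))
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["woman_id", "date", "code"], kind="mergesort").reset_index(drop=True)

    rx_frames = []
    for drug, prev in config.rx_prevalences.items():
        has = rng.random(n) < prev
        if has.any():
            dates = lmp[has] - rng.integers(1, 91, size=int(has.sum())).astype("timedelta64[D]")
            rx_frames.append(pd.DataFrame({
                "woman_id": woman_id[has], "date": dates, "atc_class": drug,
                "fda_category": config.rx_fda_category.get(drug, "none"),
            }))
    prescriptions = (
        pd.concat(rx_frames, ignore_index=True)
        .sort_values(["woman_id", "date", "atc_class"], kind="mergesort")
        .reset_index(drop=True)
        if rx_frames
        else pd.DataFrame(columns=["woman_id", "date", "atc_class", "fda_category"])
    )

    women = pd.DataFrame({
        "woman_id": woman_id, "birth_date": birth, "n_visits": visits, "death_date": death_date,
    })
    truth = pd.DataFrame({
        "woman_id": woman_id, "true_outcome": true_outcome,
        "true_lmp_date": lmp, "true_event_day": event_day,
    })
    return events, prescriptions, women, truth


def write_dataset(out_dir, events, prescriptions, women, truth) -> dict[str, Path]:
    """Write the four generator tables as UTF-8 CSV with ISO-8601 dates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("events", events), ("prescriptions", prescriptions),
                     ("women", women), ("truth", truth)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%d")
        paths[name] = p
    return paths


def expected_loss_probability(config: SimConfig, band: str) -> float:
    """Closed-form loss probability for one age band under the scaled hazard."""
    hz = np.asarray(config.baseline_weekly_hazard)
    s = config.hazard_scale()
    m = config.age_hazard_multipliers[band]
    p = 1.0 - (1.0 - hz) ** (s * m)
    return float(1.0 - np.prod(1.0 - p))
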