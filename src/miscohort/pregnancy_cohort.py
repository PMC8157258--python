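"""Pregnancy-episode construction: LMP determination, imputation, filters.

One episode is built per woman — her first pregnancy in the study window,
identified by the earliest end-of-pregnancy event.  Gestational age is the
whole-day difference ``end_date − lmp_date``.  Women with a recorded LMP
marker keep it and pass through gestational-age plausibility filters; for
the rest the LMP is imputed backwards from the end date with a fixed offset
per outcome: 280 days for delivery/postpartum and stillbirth, 74 days for a
pregnancy loss, 52 days for an ectopic pregnancy.

Plausibility windows (recorded-LMP stream only; the text excludes with
strict inequalities, so the retained ranges are closed):

* delivery/postpartum or stillbirth: gestational age in [155, 320] days;
* pregnancy loss or ectopic: gestational age in [28, 154] days.

Imputed-LMP episodes have their gestational age fixed by construction and
are not filtered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .taxonomy import CodeTaxonomy, LMP_CODE, NON_LOSS_OUTCOME_CODES, default_taxonomy

__all__ = [
    "OUTCOME_CLASSES",
    "IMPUTATION_OFFSET_DAYS",
    "impute_lmp",
    "apply_plausibility_filters",
    "select_first_pregnancy",
    "build_cohort",
    "age_band_of",
]

OUTCOME_CLASSES = ("delivery_postpartum", "stillbirth", "pregnancy_loss", "ectopic")

#: days subtracted from the end-of-pregnancy date when the LMP is missing
IMPUTATION_OFFSET_DAYS = {
    "delivery_postpartum": 280,
    "stillbirth": 280,
    "pregnancy_loss": 74,
    "ectopic": 52,
}

#: retained gestational-age windows, closed on both ends
_PLAUSIBLE_GA = {
    "delivery_postpartum": (155, 320),
    "stillbirth": (155, 320),
    "pregnancy_loss": (28, 154),
    "ectopic": (28, 154),
}


class ClassificationError(ValueError):
    """Unknown pregnancy outcome class."""


class InputError(ValueError):
    """Malformed input table (e.g. duplicate woman_id)."""


def _require_outcome(outcome_class: str) -> None:
    if outcome_class not in OUTCOME_CLASSES:
        raise ClassificationError(
            f"unknown outcome_class {outcome_class!r}; expected one of {OUTCOME_CLASSES}"
        )


def impute_lmp(end_date, outcome_class: str):
    """Impute the LMP date by pure calendar arithmetic from the end date."""
    _require_outcome(outcome_class)
    end = pd.Timestamp(end_date)
    return end - pd.Timedelta(days=IMPUTATION_OFFSET_DAYS[outcome_class])


def apply_plausibility_filters(outcome_class: str, gestational_age_days: int):
    """Return ``(keep, reason)``; ``reason`` is None when the episode is kept."""
    _require_outcome(outcome_class)
    ga = int(gestational_age_days)
    if ga < 0:
        return False, "end precedes LMP"
    lo, hi = _PLAUSIBLE_GA[outcome_class]
    if ga < lo:
        return False, f"gestational age < {lo} days"
    if ga > hi:
        return False, f"gestational age > {hi} days"
    return True, None


def age_band_of(age_years: int) -> str:
    if age_years < 30:
        return "<30"
    if age_years < 35:
        return "30-34"
    if age_years < 40:
        return "35-39"
    return ">=40"


def _code_priority(taxonomy: CodeTaxonomy) -> dict[str, int]:
    """Same-day tie-break order: loss categories 1 < 2 < 3, then ectopic,
    stillbirth, delivery; ties broken by lexicographic code."""
    prio = {code: int(cat) for code, cat in
            zip(taxonomy.table["code"], taxonomy.table["category"])}
    for code, outcome in NON_LOSS_OUTCOME_CODES.items():
        prio[code] = {"ectopic": 4, "stillbirth": 5, "delivery_postpartum": 6}[outcome]
    return prio


def _outcome_of_code(code: str, taxonomy: CodeTaxonomy) -> str | None:
    if code in NON_LOSS_OUTCOME_CODES:
        return NON_LOSS_OUTCOME_CODES[code]
    if code in taxonomy.loss_codes:
        return "pregnancy_loss"
    return None


def select_first_pregnancy(events: pd.DataFrame, taxonomy: CodeTaxonomy | None = None):
    """Pick one woman's first end-of-pregnancy event, or None.

    Deterministic under any permutation of the input rows: candidates are
    ordered by date, then tie-break priority, then code.
    """
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    prio = _code_priority(tax)
    cand = events[events["code"].isin(prio)].copy()
    if cand.empty:
        return None
    cand["date"] = pd.to_datetime(cand["date"])
    cand["_prio"] = cand["code"].map(prio)
    cand = cand.sort_values(["date", "_prio", "code"], kind="mergesort")
    row = cand.iloc[0]
    return {
        "date": row["date"],
        "code": row["code"],
        "descriptor": row.get("descriptor", ""),
        "outcome_class": _outcome_of_code(row["code"], tax),
    }


def build_cohort(
    events: pd.DataFrame,
    women: pd.DataFrame,
    taxonomy: CodeTaxonomy | None = None,
):
    """Build one pregnancy episode per woman plus an exclusion log.

    Parameters
    ----------
    events
        Columns ``woman_id, date, code, descriptor``.
    women
        Columns ``woman_id, birth_date`` (extra columns are ignored here).

    Returns
    -------
    episodes : DataFrame
        One row per retained woman: ``woman_id, lmp_date, lmp_source,
        end_date, outcome_class, gestational_age_days, age_at_lmp_years,
        age_band, end_code, end_descriptor``.
    exclusions : DataFrame
        ``woman_id, reason`` for every woman not retained.
    """
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    if women["woman_id"].duplicated().any():
        dupes = women.loc[women["woman_id"].duplicated(), "woman_id"].tolist()
        raise InputError(f"duplicate woman_id in women table: {dupes[:5]}")

    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    prio = _code_priority(tax)

    # earliest end-of-pregnancy event per woman, deterministic tie-break
    cand = ev[ev["code"].isin(prio)].copy()
    cand["_prio"] = cand["code"].map(prio)
    cand = cand.sort_values(["woman_id", "date", "_prio", "code"], kind="mergesort")
    first = cand.drop_duplicates("woman_id", keep="first")

    wom = women.copy()
    wom["birth_date"] = pd.to_datetime(wom["birth_date"])
    ep = first.merge(wom[["woman_id", "birth_date"]], on="woman_id", how="inner")
    ep = ep.rename(columns={"date": "end_date", "code": "end_code",
                            "descriptor": "end_descriptor"})
    ep["outcome_class"] = ep["end_code"].map(lambda c: _outcome_of_code(c, tax))

    exclusions = []
    no_preg = set(wom["woman_id"]) - set(ep["woman_id"])
    exclusions.extend({"woman_id": w, "reason": "no pregnancy event"} for w in sorted(no_preg))

    # recorded LMP: latest LMP marker dated on/before the end date
    lmp_ev = ev[ev["code"] == LMP_CODE][["woman_id", "date"]].rename(columns={"date": "lmp_date"})
    lmp_ev = lmp_ev.merge(ep[["woman_id", "end_date"]], on="woman_id", how="inner")
    lmp_ev = lmp_ev[lmp_ev["lmp_date"] <= lmp_ev["end_date"]]
    lmp_ev = (lmp_ev.sort_values(["woman_id", "lmp_date"], kind="mergesort")
              .drop_duplicates("woman_id", keep="last"))
    ep = ep.merge(lmp_ev[["woman_id", "lmp_date"]], on="woman_id", how="left")
    recorded = ep["lmp_date"].notna()
    ep["lmp_source"] = np.where(recorded, "recorded", "imputed")

    # impute where missing
    offsets = ep["outcome_class"].map(IMPUTATION_OFFSET_DAYS)
    imputed_lmp = ep["end_date"] - pd.to_timedelta(offsets, unit="D")
    ep["lmp_date"] = ep["lmp_date"].where(recorded, imputed_lmp)
    ep["gestational_age_days"] = (ep["end_date"] - ep["lmp_date"]).dt.days.astype(int)

    # plausibility filters on the recorded-LMP stream (vectorised form of
    # apply_plausibility_filters)
    ga = ep["gestational_age_days"].to_numpy()
    lo = ep["outcome_class"].map({k: v[0] for k, v in _PLAUSIBLE_GA.items()}).to_numpy()
    hi = ep["outcome_class"].map({k: v[1] for k, v in _PLAUSIBLE_GA.items()}).to_numpy()
    rec = (ep["lmp_source"] == "recorded").to_numpy()
    keep = ~rec | ((ga >= lo) & (ga <= hi))
    reasons = np.full(len(ep), None, dtype=object)
    reasons[rec & (ga < 0)] = "end precedes LMP"
    short = rec & (ga >= 0) & (ga < lo)
    long = rec & (ga > hi)
    reasons[short] = [f"gestational age < {v} days" for v in lo[short]]
    reasons[long] = [f"gestational age > {v} days" for v in hi[long]]

    # age at LMP in completed years (floor); childbearing range 15-49
    ep["age_at_lmp_years"] = (
        (ep["lmp_date"] - ep["birth_date"]).dt.days / 365.25
    ).astype(int)
    bad_age = (ep["age_at_lmp_years"] < 15) | (ep["age_at_lmp_years"] > 49)
    reasons = np.where(keep & bad_age.to_numpy(), "age at LMP outside 15-49", reasons)
    keep &= ~bad_age.to_numpy()

    for row, why in zip(ep.itertuples(index=False), reasons):
        if why is not None:
            exclusions.append({"woman_id": row.woman_id, "reason": why})

    ep = ep[keep].copy()
    ep["age_band"] = ep["age_at_lmp_years"].map(age_band_of)
    cols = ["woman_id", "lmp_date", "lmp_source", "end_date", "outcome_class",
            "gestational_age_days", "age_at_lmp_years", "age_band",
            "end_code", "end_descriptor"]
    episodes = ep[cols].sort_values("woman_id", kind="mergesort").reset_index(drop=True)
    excl = pd.DataFrame(exclusions, columns=["woman_id", "reason"])
    return episodes, excl
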