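"""Pregnancy-loss classification and PPV-gated case validation.

Loss events are mapped to the category/subcategory code taxonomy, a random
sample of each subcategory is checked against gold-standard labels (the
synthetic stand-in for manual chart review), and subcategories whose
positive predictive value (PPV) for miscarriage falls below the inclusion
threshold (85% by default) are excluded from the confirmed-miscarriage
pool.  Category-2 (termination-suggestive) subcategories are routed to a
TOP pool regardless of threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import CodeTaxonomy, FALLBACK_SUBCATEGORY, default_taxonomy

__all__ = [
    "PPVResult",
    "GateDecision",
    "classify_loss_event",
    "classify_losses",
    "clopper_pearson",
    "estimate_ppv",
    "simulate_review",
    "apply_ppv_gate",
    "confirmed_pool",
    "DEFAULT_PPV_THRESHOLD",
]

DEFAULT_PPV_THRESHOLD = 0.85


class EstimationError(ValueError):
    """PPV requested on an empty review sample."""


class GatingError(ValueError):
    """A populated subcategory reached the gate without a PPV estimate."""


@dataclass(frozen=True)
class PPVResult:
    subcategory: str
    n_reviewed: int
    n_confirmed: int
    ppv: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class GateDecision:
    subcategory: str
    member_count: int
    decision: str  # include_as_miscarriage | classify_as_TOP | exclude
    reason: str


def classify_loss_event(code: str, descriptor: str, taxonomy: CodeTaxonomy | None = None) -> str:
    """Assign a loss event to a taxonomy subcategory.

    The code is looked up first; unknown codes fall back to case-insensitive
    substring matching on the descriptor (most specific pattern first), and
    events matching nothing land in the catch-all subcategory 3.4.
    """
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    sub = tax.subcategory_for_code(code)
    if sub is None:
        sub = tax.subcategory_for_descriptor(descriptor)
    return sub if sub is not None else FALLBACK_SUBCATEGORY


def classify_losses(episodes: pd.DataFrame, taxonomy: CodeTaxonomy | None = None) -> pd.DataFrame:
    """Classify every pregnancy-loss episode.

    Returns a DataFrame ``woman_id, code, subcategory, category`` with one
    row per loss episode (the subcategories partition the losses).
    """
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    losses = episodes[episodes["outcome_class"] == "pregnancy_loss"]
    code_map = {r.code: str(r.subcategory) for r in tax.table.itertuples(index=False)}
    subs = [
        code_map.get(c) or classify_loss_event(c, d, tax)
        for c, d in zip(losses["end_code"], losses["end_descriptor"])
    ]
    out = pd.DataFrame({
        "woman_id": losses["woman_id"].to_numpy(),
        "code": losses["end_code"].to_numpy(),
        "subcategory": subs,
    })
    out["category"] = out["subcategory"].str.split(".").str[0].astype(int)
    return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n < 1:
        raise EstimationError("empty sample")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def estimate_ppv(
    subcategory: str,
    gold_labels,
    outcome_of_interest: str = "miscarriage",
    alpha: float = 0.05,
) -> PPVResult:
    """PPV of a subcategory from reviewed gold labels, with exact
    (Clopper–Pearson) binomial confidence interval."""
    labels = list(gold_labels)
    n = len(labels)
    if n == 0:
        raise EstimationError(f"subcategory {subcategory}: empty review sample")
    k = sum(1 for lab in labels if lab == outcome_of_interest)
    low, high = clopper_pearson(k, n, alpha)
    return PPVResult(subcategory, n, k, k / n, low, high)


def simulate_review(
    members: pd.DataFrame,
    truth: pd.DataFrame,
    review_n: int,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Draw a simple random review sample per subcategory and return its
    gold labels (keyed by subcategory).

    ``members`` is the classification table (``woman_id, subcategory``);
    ``truth`` carries ``woman_id, true_outcome``.  When a subcategory has
    fewer members than ``review_n`` the whole subcategory is reviewed
    (a census).  Seed-deterministic via ``rng``.
    """
    if review_n <= 0:
        raise EstimationError("review_n must be positive")
    gold = truth.set_index("woman_id")["true_outcome"]
    samples: dict[str, list[str]] = {}
    for sub, grp in members.groupby("subcategory", sort=True):
        ids = np.sort(grp["woman_id"].to_numpy())
        take = min(review_n, len(ids))
        chosen = rng.choice(ids, size=take, replace=False)
        samples[str(sub)] = gold.loc[chosen].tolist()
    return samples


def apply_ppv_gate(
    counts: dict[str, int],
    ppvs: dict[str, PPVResult],
    threshold: float = DEFAULT_PPV_THRESHOLD,
) -> tuple[int, list[GateDecision]]:
    """Apply the PPV inclusion rule and size the confirmed-miscarriage pool.

    Category 1 and 3 subcategories contribute all their members when their
    miscarriage PPV is at or above ``threshold``; category 2 subcategories
    are classified as TOP outright; everything else is excluded.  Returns
    ``(pool_size, decisions)``.
    """
    decisions: list[GateDecision] = []
    pool = 0
    for sub in sorted(counts):
        n = int(counts[sub])
        category = int(sub.split(".", 1)[0])
        if category == 2:
            decisions.append(GateDecision(sub, n, "classify_as_TOP",
                                          "termination-suggestive code category"))
            continue
        if sub not in ppvs:
            if n > 0:
                raise GatingError(f"subcategory {sub} has members but no PPV estimate")
            decisions.append(GateDecision(sub, 0, "exclude", "empty subcategory"))
            continue
        ppv = ppvs[sub].ppv
        if ppv >= threshold:
            pool += n
            decisions.append(GateDecision(sub, n, "include_as_miscarriage",
                                          f"PPV {ppv:.2f} >= {threshold:.2f}"))
        else:
            decisions.append(GateDecision(sub, n, "exclude",
                                          f"PPV {ppv:.2f} < {threshold:.2f}"))
    return pool, decisions


def confirmed_pool(
    classified: pd.DataFrame,
    truth: pd.DataFrame,
    review_n: int,
    rng: np.random.Generator,
    threshold: float = DEFAULT_PPV_THRESHOLD,
):
    """Run review + gate and return the confirmed-miscarriage woman ids.

    Returns
    -------
    pool_ids : set[int]
        Members of all subcategories admitted as miscarriage.
    ppv_results : dict[str, PPVResult]
    decisions : list[GateDecision]
    """
    samples = simulate_review(classified, truth, review_n, rng)
    ppvs = {sub: estimate_ppv(sub, labels) for sub, labels in samples.items()}
    counts = classified["subcategory"].value_counts().to_dict()
    _, decisions = apply_ppv_gate(counts, ppvs, threshold)
    included = {d.subcategory for d in decisions if d.decision == "include_as_miscarriage"}
    pool_ids = set(classified.loc[classified["subcategory"].isin(included), "woman_id"])
    return pool_ids, ppvs, decisions
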