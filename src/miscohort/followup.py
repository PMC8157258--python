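"""Follow-up construction and miscarriage incidence estimation.

Each pregnancy episode contributes follow-up from the LMP (day 0) to the
first of: the pregnancy-loss event, gestational day 154 (week 22, the upper
limit for a loss), or death.  Miscarriage is the event of interest only for
members of the confirmed pool; other losses (TOP, unspecified, ectopic) end
follow-up and are treated as censoring in the single-event Kaplan–Meier and
rate analyses (cause-specific framing, not a competing-risk estimator).

Estimators
----------
* person-week incidence rates with exact Poisson confidence intervals;
* Kaplan–Meier product-limit curve with Greenwood variance;
* k-group log-rank test with hypergeometric variance;
* weekly event histogram (weeks = floor(days / 7); day-154 events count
  as events, not censorings);
* cumulative incidence as 1 − S(154) with a log-scale Greenwood interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FollowUpError",
    "EstimationError",
    "IncidenceEstimate",
    "KMCurve",
    "build_followup",
    "incidence_rate",
    "poisson_exact_ci",
    "km_estimate",
    "logrank_test",
    "weekly_event_distribution",
    "cumulative_incidence",
]

#: follow-up ends at gestational day 154 (22 weeks) at the latest
MAX_FOLLOWUP_DAY = 154


class FollowUpError(ValueError):
    pass


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class IncidenceEstimate:
    n_events: int
    person_weeks: float
    rate_per_1000pw: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood variance of S(t)
    cumvar_log: np.ndarray = field(repr=False)  # sum d/(n(n-d)), for log-scale CIs

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def quantile(self, q: float) -> float:
        """Smallest event time t with S(t) <= 1 - q (nan if never reached)."""
        below = np.nonzero(self.survival <= 1.0 - q)[0]
        return float(self.times[below[0]]) if below.size else float("nan")


def build_followup(
    episodes: pd.DataFrame,
    confirmed_ids,
    women: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build one follow-up record per episode.

    Exit is the first of {loss/ectopic event day, day 154, death day};
    the event is ``miscarriage`` iff the terminating loss belongs to the
    confirmed pool, ``other_loss`` for any other loss or ectopic exit, and
    ``censored`` otherwise.  ``women`` (optional) supplies ``death_date``.
    """
    confirmed = set(confirmed_ids)
    ep = episodes.copy()
    ga = ep["gestational_age_days"].to_numpy()
    if (ga < 0).any():
        bad = ep.loc[ga < 0, "woman_id"].tolist()
        raise FollowUpError(f"pregnancy end precedes LMP for women {bad[:5]}")

    is_loss = (ep["outcome_class"] == "pregnancy_loss").to_numpy()
    is_ect = (ep["outcome_class"] == "ectopic").to_numpy()
    exit_day = np.where(is_loss | is_ect, np.minimum(ga, MAX_FOLLOWUP_DAY), MAX_FOLLOWUP_DAY)
    in_pool = ep["woman_id"].isin(confirmed).to_numpy()
    event = np.where(is_loss & in_pool, "miscarriage",
             np.where(is_loss | is_ect, "other_loss", "censored"))

    if women is not None and "death_date" in women.columns:
        dd = ep[["woman_id", "lmp_date"]].merge(
            women[["woman_id", "death_date"]], on="woman_id", how="left")
        death_day = (pd.to_datetime(dd["death_date"]) - pd.to_datetime(dd["lmp_date"])).dt.days
        death_day = death_day.to_numpy(dtype=float)
        dies_first = np.isfinite(death_day) & (death_day > 0) & (death_day < exit_day)
        exit_day = np.where(dies_first, death_day, exit_day).astype(int)
        event = np.where(dies_first, "censored", event)

    out = pd.DataFrame({
        "woman_id": ep["woman_id"].to_numpy(),
        "entry_day": 0,
        "exit_day": exit_day.astype(int),
        "event": event,
    })
    for col in ("age_band", "lmp_source", "outcome_class"):
        if col in ep.columns:
            out[col] = ep[col].to_numpy()
    if (out["exit_day"] <= 0).any():
        raise FollowUpError("follow-up of zero or negative length")
    return out


def poisson_exact_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (chi-square inversion) confidence bounds for a Poisson count."""
    low = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k) / 2)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2)
    return low, high


def incidence_rate(
    records: pd.DataFrame,
    event_of_interest: str = "miscarriage",
    alpha: float = 0.05,
) -> IncidenceEstimate:
    """Events per 1000 person-weeks with exact Poisson confidence interval."""
    if len(records) == 0:
        raise EstimationError("no follow-up records")
    pw = float(records["exit_day"].sum()) / 7.0
    if pw <= 0:
        raise EstimationError("zero person-time")
    k = int((records["event"] == event_of_interest).sum())
    lo, hi = poisson_exact_ci(k, alpha)
    return IncidenceEstimate(k, pw, k / pw * 1000.0, lo / pw * 1000.0, hi / pw * 1000.0)


def km_estimate(durations, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator with Greenwood variance.

    ``events`` is a boolean/0-1 array (1 = event of interest, 0 = censored).
    """
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events).astype(bool)
    if t.size == 0:
        raise EstimationError("no follow-up records")
    order = np.argsort(t, kind="mergesort")
    t, d = t[order], d[order]
    event_times = np.unique(t[d])
    n = t.size
    n_risk = np.empty(event_times.size, dtype=int)
    n_ev = np.empty(event_times.size, dtype=int)
    for i, et in enumerate(event_times):
        n_risk[i] = int((t >= et).sum())
        n_ev[i] = int(((t == et) & d).sum())
    frac = n_ev / n_risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_risk > n_ev, n_ev / (n_risk * (n_risk - n_ev)), np.inf)
    cumvar = np.cumsum(gw_terms)
    var = np.zeros_like(surv)
    pos = surv > 0
    var[pos] = surv[pos] ** 2 * cumvar[pos]
    return KMCurve(event_times, n_risk, n_ev, surv, var, cumvar)


def logrank_test(durations, events, groups):
    """k-sample log-rank test.

    Returns ``(chi_square, df, p_value)``; the statistic pools the distinct
    event times and uses the hypergeometric variance of the per-group event
    counts.
    """
    t = np.asarray(durations, dtype=float)
    d = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise EstimationError("log-rank test needs at least two groups")
    event_times = np.unique(t[d])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        dt = int((d & (t == et)).sum())
        if n < 1 or dt == 0:
            continue
        ng = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        og = np.array([((t == et) & d & (g == lab)).sum() for lab in labels], dtype=float)
        O += og
        E += dt * ng / n
        if n > 1:
            p = ng / n
            V += dt * (n - dt) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def weekly_event_distribution(
    records: pd.DataFrame, event_of_interest: str = "miscarriage"
) -> pd.DataFrame:
    """Histogram of event gestational weeks (week = floor(exit_day / 7))."""
    ev = records[records["event"] == event_of_interest]
    weeks = (ev["exit_day"] // 7).astype(int)
    counts = weeks.value_counts().sort_index()
    out = pd.DataFrame({"week": counts.index, "n": counts.to_numpy()})
    out["proportion"] = out["n"] / out["n"].sum() if len(out) else []
    return out.reset_index(drop=True)


def cumulative_incidence(
    records: pd.DataFrame,
    event_of_interest: str = "miscarriage",
    at_day: int = MAX_FOLLOWUP_DAY,
    alpha: float = 0.05,
):
    """Cumulative incidence by ``at_day`` as the Kaplan–Meier complement.

    Competing losses censor at exit.  The confidence interval transforms a
    log-scale Greenwood interval for S(t):  exp(log S ± z·se(log S)).
    Returns ``(estimate, ci_low, ci_high)``.
    """
    if len(records) == 0:
        raise EstimationError("no follow-up records")
    curve = km_estimate(records["exit_day"], records["event"] == event_of_interest)
    if curve.times.size == 0:
        return 0.0, 0.0, 0.0
    idx = np.searchsorted(curve.times, at_day, side="right") - 1
    if idx < 0:
        return 0.0, 0.0, 0.0
    s = float(curve.survival[idx])
    if s <= 0:
        return 1.0, 1.0, 1.0
    se_log = float(np.sqrt(curve.cumvar_log[idx]))
    z = stats.norm.ppf(1 - alpha / 2)
    s_hi = min(1.0, float(np.exp(np.log(s) + z * se_log)))
    s_lo = float(np.exp(np.log(s) - z * se_log))
    return 1.0 - s, 1.0 - s_hi, 1.0 - s_lo
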