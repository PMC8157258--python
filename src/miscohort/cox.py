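"""Covariate ascertainment and Cox proportional-hazards regression.

The Cox partial likelihood is maximised by Newton–Raphson with the Efron
correction for tied event times (Breslow available as an option).  Standard
errors come from the inverse observed information; hazard ratios are
``exp(coef)`` with Wald 95% intervals.

Covariate ascertainment follows the study windows: condition flags from any
coded event strictly before the LMP date; drug-exposure flags from
prescriptions in the 90-day pre-pregnancy window ``[LMP−90, LMP)`` (closed
on the −90 side, open at the LMP); metabolic and psychiatric antecedent
groups as unions of their member conditions.  The reporting layer fits one
exposure at a time together with the fixed adjustment set {age band, PCP
visit band, year of LMP}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import CodeTaxonomy, LMP_CODE, NON_LOSS_OUTCOME_CODES, default_taxonomy

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "SeparationError",
    "VISIT_BANDS",
    "visit_band_of",
    "ascertain_covariates",
    "build_design",
    "fit_cox",
    "hazard_ratio_table",
]

VISIT_BANDS = ("0-1", "2-4", "5-9", ">=10")

METABOLIC_CONDITIONS = ("obesity", "diabetes", "hypercholesterolemia", "hypertension")
PSYCHIATRIC_CONDITIONS = ("epilepsy", "adhd", "anxiety", "depression", "eating_disorders")

#: category ordering for the banded covariates (reference level first)
CATEGORY_ORDERS = {
    "age_band": ("<30", "30-34", "35-39", ">=40"),
    "visit_band": VISIT_BANDS,
}


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; message carries the gradient norm."""


class SeparationError(ConvergenceError):
    """Monotone likelihood (complete separation): no finite estimate exists."""


@dataclass(frozen=True)
class CoxFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    score_norm: float
    ties: str

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame({
            "covariate": self.names, "coef": self.coef, "se": self.se,
            "hr": self.hr, "ci_low": lo, "ci_high": hi,
        })


def visit_band_of(n_visits: int) -> str:
    if n_visits <= 1:
        return "0-1"
    if n_visits <= 4:
        return "2-4"
    if n_visits <= 9:
        return "5-9"
    return ">=10"


def ascertain_covariates(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    women: pd.DataFrame,
    taxonomy: CodeTaxonomy | None = None,
) -> pd.DataFrame:
    """One covariate row per episode.

    Returns a DataFrame keyed by ``woman_id`` with ``age_band``,
    ``visit_band``, ``lmp_year``, one ``cond_*`` flag per condition code
    seen in the events, the two antecedent group flags, one ``rx_*`` flag
    per drug class, and the ``any_drug`` / ``dx_drug`` summaries.
    """
    tax = taxonomy if taxonomy is not None else default_taxonomy()
    outcome_codes = set(tax.loss_codes) | set(NON_LOSS_OUTCOME_CODES) | {LMP_CODE}

    base = episodes[["woman_id", "lmp_date", "age_band"]].copy()
    base["lmp_date"] = pd.to_datetime(base["lmp_date"])
    base["lmp_year"] = base["lmp_date"].dt.year

    wom = women[["woman_id", "n_visits"]].copy()
    wom["visit_band"] = wom["n_visits"].map(visit_band_of)
    out = base.merge(wom[["woman_id", "visit_band"]], on="woman_id", how="left")
    out["visit_band"] = out["visit_band"].fillna("0-1")

    # condition flags: any coded event strictly before the LMP date
    ev = events[~events["code"].isin(outcome_codes)].copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev.merge(base[["woman_id", "lmp_date"]], on="woman_id", how="inner")
    ev = ev[ev["date"] < ev["lmp_date"]]
    conditions = sorted(ev["code"].unique())
    flag = ev.assign(v=True).pivot_table(
        index="woman_id", columns="code", values="v", aggfunc="any", fill_value=False
    ) if len(ev) else pd.DataFrame()
    for cond in conditions:
        col = flag[cond] if cond in getattr(flag, "columns", []) else None
        out[f"cond_{cond}"] = (
            out["woman_id"].map(col).eq(True) if col is not None else False
        )
    for cond in set(METABOLIC_CONDITIONS) | set(PSYCHIATRIC_CONDITIONS):
        if f"cond_{cond}" not in out.columns:
            out[f"cond_{cond}"] = False
    out["metabolic_antecedents"] = np.logical_or.reduce(
        [out[f"cond_{c}"].to_numpy() for c in METABOLIC_CONDITIONS])
    out["psychiatric_antecedents"] = np.logical_or.reduce(
        [out[f"cond_{c}"].to_numpy() for c in PSYCHIATRIC_CONDITIONS])

    # drug flags in the 90-day pre-pregnancy window [LMP-90, LMP)
    rx = prescriptions.copy()
    if "date" in rx.columns:
        before = len(rx)
        rx = rx[rx["date"].notna()]
        if len(rx) < before:
            import warnings
            warnings.warn(f"dropped {before - len(rx)} undated prescription rows")
    if len(rx):
        rx["date"] = pd.to_datetime(rx["date"])
        rx = rx.merge(base[["woman_id", "lmp_date"]], on="woman_id", how="inner")
        window = (rx["date"] >= rx["lmp_date"] - pd.Timedelta(days=90)) & (rx["date"] < rx["lmp_date"])
        rx = rx[window]
    for drug in sorted(rx["atc_class"].unique()) if len(rx) else []:
        ids = set(rx.loc[rx["atc_class"] == drug, "woman_id"])
        out[f"rx_{drug}"] = out["woman_id"].isin(ids)
    out["any_drug"] = (
        out["woman_id"].isin(set(rx["woman_id"])) if len(rx) else False
    )
    dx_ids = set(rx.loc[rx["fda_category"].isin(["D", "X"]), "woman_id"]) if len(rx) else set()
    out["dx_drug"] = out["woman_id"].isin(dx_ids)
    return out.drop(columns=["lmp_date"])


def build_design(
    df: pd.DataFrame,
    covariates,
    references: dict[str, str] | None = None,
):
    """Expand covariates into a numeric design matrix.

    Boolean/numeric columns enter as-is; string/categorical columns are
    dummy-coded against a reference level (first level of the known band
    orderings, otherwise the lexicographically smallest value).  Returns
    ``(X, names)``.
    """
    refs = dict(references or {})
    cols, names = [], []
    for cov in covariates:
        s = df[cov]
        if s.dtype == bool or np.issubdtype(s.dtype, np.number):
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
            continue
        levels = list(CATEGORY_ORDERS.get(cov, sorted(s.astype(str).unique())))
        ref = refs.get(cov, levels[0])
        vals = s.astype(str)
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _partial_loglik_parts(beta, X, t, d, ties):
    """Log partial likelihood, score and observed information (Efron/Breslow).

    Arrays must be pre-sorted by ascending time.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    uniq, starts = np.unique(t, return_index=True)
    bounds = np.append(starts, n)
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    for j in range(uniq.size - 1, -1, -1):
        sl = slice(bounds[j], bounds[j + 1])
        Xg, wg = X[sl], w[sl]
        S0 += wg.sum()
        S1 += wg @ Xg
        S2 += (Xg * wg[:, None]).T @ Xg
        ev = d[sl]
        de = int(ev.sum())
        if de == 0:
            continue
        Xe, we = Xg[ev], wg[ev]
        s0, s1 = we.sum(), we @ Xe
        s2 = (Xe * we[:, None]).T @ Xe
        ll += float(eta[sl][ev].sum())
        grad += Xe.sum(axis=0)
        fracs = np.arange(de) / de if ties == "efron" else np.zeros(de)
        for f in fracs:
            denom = S0 - f * s0
            n1 = S1 - f * s1
            n2 = S2 - f * s2
            ll -= np.log(denom)
            grad -= n1 / denom
            info += n2 / denom - np.outer(n1, n1) / denom**2
    return ll, grad, info


def fit_cox(
    data: pd.DataFrame,
    covariates,
    duration_col: str = "exit_day",
    event_col: str = "event_flag",
    ties: str = "efron",
    references: dict[str, str] | None = None,
    max_iter: int = 100,
    tol_score: float = 1e-9,
    tol_loglik: float = 1e-10,
) -> CoxFit:
    """Fit the Cox model by Newton–Raphson on the partial likelihood.

    ``event_col`` must be boolean/0-1.  Convergence requires the maximum
    absolute score below ``tol_score`` or a relative log-likelihood change
    below ``tol_loglik``; otherwise a :class:`ConvergenceError` is raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    X, names = build_design(data, covariates, references)
    t = data[duration_col].to_numpy(dtype=float)
    d = data[event_col].to_numpy(dtype=bool)
    if d.sum() == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    spans = X.max(axis=0) - X.min(axis=0) if len(X) else np.array([])
    if (spans == 0).any():
        const = [names[i] for i in np.nonzero(spans == 0)[0]]
        raise ValueError(f"constant covariates in design: {const}")

    order = np.argsort(t, kind="mergesort")
    X, t, d = X[order], t[order], d[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _partial_loglik_parts(beta, X, t, d, ties)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _partial_loglik_parts(cand, X, t, d, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll_prev = cand, ll
        ll, grad, info = ll_new, grad_new, info_new
        if np.abs(beta).max() > 30:
            raise SeparationError(
                "coefficients diverging (complete separation?); no estimates reported"
            )
        score_norm = float(np.abs(grad).max())
        rel = abs(ll - ll_prev) / (abs(ll_prev) + 1e-300)
        if score_norm < tol_score or rel < tol_loglik:
            if np.abs(beta).max() > 15:
                # |log HR| this large only arises under monotone likelihood
                raise SeparationError(
                    "coefficient diverged (complete separation); no estimates reported"
                )
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return CoxFit(tuple(names), beta, se, float(ll), it, score_norm, ties)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations; |score| = {np.abs(grad).max():.3e}"
    )


def hazard_ratio_table(
    data: pd.DataFrame,
    exposures,
    adjustment=("age_band", "visit_band", "lmp_year"),
    duration_col: str = "exit_day",
    event_col: str = "event_flag",
    ties: str = "efron",
    min_prevalence: float = 0.005,
    year_coding: str = "categorical",
) -> pd.DataFrame:
    """Adjusted hazard-ratio report, one exposure at a time.

    Each binary exposure is fitted in a model containing itself plus the
    fixed adjustment set; the banded adjustment covariates are reported
    from the adjustment-only model.  Exposures with prevalence below
    ``min_prevalence`` (0.5% by default) are omitted with a note.  Returns
    one row per covariate level with event/non-event counts, percentages,
    HR and 95% CI.
    """
    data = data.copy()
    if year_coding == "categorical":
        data["lmp_year"] = data["lmp_year"].astype(str)
    elif year_coding == "linear":
        data["lmp_year"] = data["lmp_year"].astype(float)
    else:
        raise ValueError(f"unknown year_coding {year_coding!r}")

    is_event = data[event_col].astype(bool)
    n_event = int(is_event.sum())
    n_non = int((~is_event).sum())

    def cell(mask):
        ne = int((mask & is_event).sum())
        nn = int((mask & ~is_event).sum())
        return ne, round(100 * ne / n_event, 1) if n_event else 0.0, \
            nn, round(100 * nn / n_non, 1) if n_non else 0.0

    rows = []
    base_fit = fit_cox(data, list(adjustment), duration_col, event_col, ties=ties)
    base = base_fit.summary().set_index("covariate")
    for cov in ("age_band", "visit_band"):
        if cov not in adjustment:
            continue
        levels = CATEGORY_ORDERS[cov]
        for i, lev in enumerate(levels):
            mask = data[cov].astype(str) == lev
            ne, pe, nn, pn = cell(mask)
            if i == 0:
                rows.append({"covariate": cov, "level": lev, "n_event": ne,
                             "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                             "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                             "n_iter": base_fit.n_iter, "note": "reference"})
            else:
                r = base.loc[f"{cov}[{lev}]"]
                rows.append({"covariate": cov, "level": lev, "n_event": ne,
                             "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                             "hr": r["hr"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                             "n_iter": base_fit.n_iter, "note": ""})

    for exp_col in exposures:
        flag = data[exp_col].astype(bool)
        prev = float(flag.mean())
        ne, pe, nn, pn = cell(flag)
        if flag.all() or not flag.any():
            rows.append({"covariate": exp_col, "level": "yes", "n_event": ne,
                         "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n_iter": 0, "note": "no contrast: flag constant"})
            continue
        if prev < min_prevalence:
            rows.append({"covariate": exp_col, "level": "yes", "n_event": ne,
                         "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n_iter": 0,
                         "note": f"prevalence {100 * prev:.2f}% < {100 * min_prevalence:.1f}%"})
            continue
        if (flag & is_event).sum() == 0 or (~flag & is_event).sum() == 0:
            rows.append({"covariate": exp_col, "level": "yes", "n_event": ne,
                         "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n_iter": 0, "note": "no events in one exposure group"})
            continue
        try:
            fit = fit_cox(data, [exp_col, *adjustment], duration_col, event_col, ties=ties)
        except (ValueError, ConvergenceError) as err:
            rows.append({"covariate": exp_col, "level": "yes", "n_event": ne,
                         "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n_iter": 0, "note": f"not fitted: {err}"})
            continue
        r = fit.summary().set_index("covariate").loc[exp_col]
        rows.append({"covariate": exp_col, "level": "yes", "n_event": ne,
                     "pct_event": pe, "n_nonevent": nn, "pct_nonevent": pn,
                     "hr": r["hr"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                     "n_iter": fit.n_iter, "note": ""})
    return pd.DataFrame(rows)
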