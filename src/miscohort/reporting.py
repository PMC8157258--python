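"""Pipeline orchestration and table-style reporting.

Runs the stages end-to-end — simulate, build cohort, classify and gate the
losses, construct follow-up and incidence outputs, fit the Cox models —
writing each stage's tables as CSV plus a JSON run manifest (config hash,
seed, per-stage row counts, output checksums) for reproducibility.

Display conventions: percentages are rounded to one decimal, rates and
hazard ratios to two.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cox import ascertain_covariates, hazard_ratio_table
from .followup import (
    build_followup,
    cumulative_incidence,
    incidence_rate,
    km_estimate,
    weekly_event_distribution,
)
from .loss_classifier import classify_losses, confirmed_pool
from .pregnancy_cohort import build_cohort
from .synthetic_ehr import SimConfig, generate_cohort, write_dataset
from .taxonomy import default_taxonomy

__all__ = [
    "percentage",
    "outcome_percentages",
    "baseline_table",
    "analyze_followup",
    "run_pipeline",
]


def percentage(n: float, denominator: float, decimals: int = 1) -> float:
    """Share of ``n`` in ``denominator`` as a percentage, display-rounded."""
    if denominator == 0:
        return 0.0
    return round(100.0 * n / denominator, decimals)


def outcome_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentage composition of an outcome count table."""
    total = sum(counts.values())
    return {k: percentage(v, total, decimals) for k, v in counts.items()}


def baseline_table(
    episodes: pd.DataFrame,
    covariates: pd.DataFrame,
    confirmed_ids,
) -> pd.DataFrame:
    """Baseline characteristics by miscarriage status x LMP-date entry.

    Counts and within-column percentages for age bands, condition flags,
    antecedent groups and drug exposures, in four columns: confirmed
    miscarriage vs remaining cohort, each split by recorded/imputed LMP.
    """
    df = episodes.merge(covariates.drop(columns=["age_band"]), on="woman_id", how="left")
    df["_miscarriage"] = df["woman_id"].isin(set(confirmed_ids))
    groups = {
        "miscarriage_recorded": (df["_miscarriage"]) & (df["lmp_source"] == "recorded"),
        "miscarriage_imputed": (df["_miscarriage"]) & (df["lmp_source"] == "imputed"),
        "rest_recorded": (~df["_miscarriage"]) & (df["lmp_source"] == "recorded"),
        "rest_imputed": (~df["_miscarriage"]) & (df["lmp_source"] == "imputed"),
    }
    import warnings
    characteristics: list[tuple[str, pd.Series]] = []
    for band in ("<30", "30-34", "35-39", ">=40"):
        characteristics.append((f"age {band}", df["age_band"] == band))
    flag_cols = [c for c in df.columns if c.startswith(("cond_", "rx_"))]
    flag_cols += ["metabolic_antecedents", "psychiatric_antecedents", "any_drug", "dx_drug"]
    for col in flag_cols:
        if col in df.columns:
            characteristics.append((col, df[col].fillna(False).astype(bool)))

    rows = []
    for name, mask in characteristics:
        row: dict[str, object] = {"characteristic": name}
        for gname, gmask in groups.items():
            denom = int(gmask.sum())
            n = int((mask & gmask).sum())
            row[f"{gname}_n"] = n
            row[f"{gname}_pct"] = percentage(n, denom) if denom else 0.0
        rows.append(row)
    for gname, gmask in groups.items():
        if gmask.sum() == 0:
            warnings.warn(f"baseline table group {gname!r} is empty; column is all zeros")
    return pd.DataFrame(rows)


def analyze_followup(
    episodes: pd.DataFrame,
    pool_ids,
    covariates: pd.DataFrame,
    women: pd.DataFrame | None = None,
    strata=("age_band", "metabolic_antecedents", "psychiatric_antecedents",
            "any_drug", "dx_drug"),
):
    """Survival/incidence outputs: follow-up records, incidence report
    (overall and per stratum, restricted to recorded-LMP women as in the
    stratified study analyses), KM curves by age band, weekly histogram."""
    records = build_followup(episodes, pool_ids, women)
    cov = records.merge(covariates.drop(columns=["age_band"]), on="woman_id", how="left")
    rec = cov[cov["lmp_source"] == "recorded"]

    inc_rows = []

    def add_row(label, subset):
        if len(subset) == 0:
            return
        est = incidence_rate(subset)
        ci, ci_lo, ci_hi = cumulative_incidence(subset)
        inc_rows.append({
            "stratum": label, "n_women": len(subset), "n_events": est.n_events,
            "person_weeks": round(est.person_weeks, 1),
            "rate_per_1000pw": round(est.rate_per_1000pw, 2),
            "rate_ci_low": round(est.ci_low, 2), "rate_ci_high": round(est.ci_high, 2),
            "cumulative_incidence_pct": percentage(ci, 1.0),
            "cuminc_ci_low_pct": percentage(ci_lo, 1.0),
            "cuminc_ci_high_pct": percentage(ci_hi, 1.0),
        })

    add_row("overall", cov)
    add_row("lmp_recorded", rec)
    add_row("lmp_imputed", cov[cov["lmp_source"] == "imputed"])
    for stratum in strata:
        if stratum not in rec.columns:
            continue
        vals = rec[stratum]
        levels = (
            ("<30", "30-34", "35-39", ">=40") if stratum == "age_band"
            else sorted(vals.dropna().unique())
        )
        for lev in levels:
            add_row(f"{stratum}={lev}", rec[vals == lev])
    incidence_report = pd.DataFrame(inc_rows)

    km_rows = []
    for label, subset in [("overall", rec)] + [
        (f"age_band={b}", rec[rec["age_band"] == b]) for b in ("<30", "30-34", "35-39", ">=40")
    ]:
        if len(subset) == 0:
            continue
        curve = km_estimate(subset["exit_day"], subset["event"] == "miscarriage")
        km_rows.append(pd.DataFrame({
            "stratum": label, "day": curve.times.astype(int),
            "n_risk": curve.n_risk, "n_events": curve.n_events,
            "survival": curve.survival, "std": np.sqrt(curve.variance),
        }))
    km_curves = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame()
    week_hist = weekly_event_distribution(rec)
    return records, incidence_report, km_curves, week_hist


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: SimConfig, out_dir, seed: int | None = None):
    """Run simulate → build-cohort → classify → analyze → cox → report.

    All randomness derives from the single top-level seed (``seed``
    overrides ``config.seed``), split deterministically per stage.  Returns
    ``(manifest, outputs)`` where ``outputs`` maps table names to the
    DataFrames written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    top_seed = config.seed if seed is None else seed
    sim_seed, review_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(top_seed).spawn(2)
    )
    tax = default_taxonomy()

    events, prescriptions, women, truth = generate_cohort(config, seed=sim_seed, taxonomy=tax)
    write_dataset(out, events, prescriptions, women, truth)
    tax.to_csv(out / "taxonomy.csv")

    episodes, exclusions = build_cohort(events, women, tax)
    classified = classify_losses(episodes, tax)
    pool_ids, ppvs, decisions = confirmed_pool(
        classified, truth, config.review_n, np.random.default_rng(review_seed)
    )
    covariates = ascertain_covariates(episodes, events, prescriptions, women, tax)
    records, incidence_report, km_curves, week_hist = analyze_followup(
        episodes, pool_ids, covariates, women
    )

    cox_data = records.merge(covariates.drop(columns=["age_band"]), on="woman_id", how="left")
    cox_data = cox_data[cox_data["lmp_source"] == "recorded"].copy()
    cox_data["event_flag"] = cox_data["event"] == "miscarriage"
    exposures = [c for c in cox_data.columns if c.startswith(("cond_", "rx_"))]
    exposures += ["metabolic_antecedents", "psychiatric_antecedents", "any_drug", "dx_drug"]
    hr_table = hazard_ratio_table(cox_data, exposures)
    hr_table["hr"] = hr_table["hr"].round(2)
    hr_table[["ci_low", "ci_high"]] = hr_table[["ci_low", "ci_high"]].round(2)

    ppv_report = pd.DataFrame([dataclasses.asdict(p) for p in ppvs.values()])
    gate_report = pd.DataFrame([dataclasses.asdict(d) for d in decisions])
    base_table = baseline_table(episodes, covariates, pool_ids)

    outputs = {
        "cohort": episodes, "exclusions": exclusions, "classification": classified,
        "ppv_report": ppv_report, "gate_decisions": gate_report,
        "followup": records, "incidence_report": incidence_report,
        "km_curves": km_curves, "week_histogram": week_hist,
        "hr_table": hr_table, "baseline_table": base_table,
    }
    for name, df in outputs.items():
        df.to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%d")

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": top_seed,
        "stage_rows": {
            "events": len(events), "prescriptions": len(prescriptions),
            "women": len(women), "cohort": len(episodes),
            "excluded": len(exclusions), "losses": len(classified),
            "confirmed_pool": len(pool_ids), "followup": len(records),
        },
        "output_sha256": {name: _sha256(out / f"{name}.csv") for name in outputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest, outputs
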