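"""Follow-up construction and the survival estimators, checked against
hand computations, tail-probability inversion oracles and an independent
survival library."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from miscohort.followup import (
    EstimationError,
    FollowUpError,
    build_followup,
    cumulative_incidence,
    incidence_rate,
    km_estimate,
    logrank_test,
    poisson_exact_ci,
    weekly_event_distribution,
)
from miscohort.synthetic_ehr import SimConfig


def _episodes(rows):
    df = pd.DataFrame(rows, columns=["woman_id", "outcome_class", "gestational_age_days"])
    df["lmp_date"] = pd.Timestamp("2010-01-01")
    df["lmp_source"] = "recorded"
    df["age_band"] = "<30"
    return df


def _records(exits, events):
    return pd.DataFrame({
        "woman_id": range(1, len(exits) + 1),
        "entry_day": 0, "exit_day": exits, "event": events,
    })


class TestBuildFollowup:
    def test_exit_and_event_coding(self):
        eps = _episodes([
            (1, "pregnancy_loss", 70),    # confirmed miscarriage
            (2, "delivery_postpartum", 280),
            (3, "pregnancy_loss", 60),    # TOP-coded, not in pool
            (4, "ectopic", 40),
            (5, "stillbirth", 200),
        ])
        rec = build_followup(eps, confirmed_ids={1}).set_index("woman_id")
        assert rec.loc[1, "exit_day"] == 70 and rec.loc[1, "event"] == "miscarriage"
        assert rec.loc[2, "exit_day"] == 154 and rec.loc[2, "event"] == "censored"
        assert rec.loc[3, "exit_day"] == 60 and rec.loc[3, "event"] == "other_loss"
        assert rec.loc[4, "exit_day"] == 40 and rec.loc[4, "event"] == "other_loss"
        assert rec.loc[5, "exit_day"] == 154 and rec.loc[5, "event"] == "censored"

    def test_death_censors_before_event(self):
        eps = _episodes([(1, "pregnancy_loss", 70)])
        women = pd.DataFrame({
            "woman_id": [1],
            "death_date": [pd.Timestamp("2010-01-01") + pd.Timedelta(days=50)],
        })
        rec = build_followup(eps, {1}, women)
        assert rec.loc[0, "exit_day"] == 50 and rec.loc[0, "event"] == "censored"

    def test_negative_gestation_raises(self):
        with pytest.raises(FollowUpError):
            build_followup(_episodes([(1, "pregnancy_loss", -3)]), set())


class TestIncidenceRate:
    def test_zero_events_zero_rate(self):
        est = incidence_rate(_records([154] * 5, ["censored"] * 5))
        assert est.rate_per_1000pw == 0.0 and est.ci_low == 0.0

    def test_hand_arithmetic(self):
        # 3 women followed 10 weeks each, 1 event: 1/30 x 1000
        est = incidence_rate(_records([70, 70, 70], ["miscarriage", "censored", "censored"]))
        assert est.person_weeks == pytest.approx(30.0)
        assert est.rate_per_1000pw == pytest.approx(1000 / 30)

    def test_poisson_ci_matches_tail_inversion(self):
        def bisect(f, lo, hi):
            for _ in range(200):
                mid = (lo + hi) / 2
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        for k in (25, 1, 7):
            lo, hi = poisson_exact_ci(k)
            # lower: P(X >= k | mu) = alpha/2 ; upper: P(X <= k | mu) = alpha/2
            expect_lo = bisect(lambda mu: 0.025 - stats.poisson.sf(k - 1, mu), 0, 5 * k + 10)
            expect_hi = bisect(lambda mu: stats.poisson.cdf(k, mu) - 0.025, 0, 5 * k + 20)
            assert lo == pytest.approx(expect_lo, abs=1e-6)
            assert hi == pytest.approx(expect_hi, abs=1e-6)

    def test_empty_or_zero_person_time_raises(self):
        with pytest.raises(EstimationError):
            incidence_rate(_records([], []))

    def test_person_time_order_invariance(self):
        rec = _records([70, 100, 154, 33], ["miscarriage", "censored", "censored", "other_loss"])
        shuffled = rec.sample(frac=1.0, random_state=1)
        assert incidence_rate(rec) == incidence_rate(shuffled)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curve = km_estimate([10, 20, 30], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(25) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([6, 8, 10, 10, 10], [1, 1, 0, 0, 0])
        assert curve.survival_at(6) == pytest.approx(0.8)
        assert curve.survival_at(8) == pytest.approx(0.6)
        assert curve.survival_at(9.5) == pytest.approx(0.6)
        # Greenwood by hand: S(8)^2 * (1/(5*4) + 1/(4*3))
        assert curve.variance[1] == pytest.approx(0.36 * (1 / 20 + 1 / 12))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(21)
        t = rng.integers(1, 120, 300)
        d = rng.random(300) < 0.5
        curve = km_estimate(t, d)
        kmf = KaplanMeierFitter().fit(t, d)
        ref = kmf.survival_function_["KM_estimate"]
        ours = np.array([curve.survival_at(x) for x in ref.index])
        assert np.abs(ours - ref.to_numpy()).max() < 1e-10

    def test_median_and_iqr_extractable(self):
        curve = km_estimate([2, 4, 6, 8], [1, 1, 1, 1])
        assert curve.quantile(0.5) == 4
        assert curve.quantile(0.25) == 2
        assert curve.quantile(0.75) == 6


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [5, 8, 12, 20, 5, 8, 12, 20]
        d = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, df, p = logrank_test(t, d, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_single_event_time_closed_form(self):
        # one event at t=5 in group A; both groups at risk (2 vs 3 subjects)
        t = [5, 9, 9, 9, 9]
        d = [1, 0, 0, 0, 0]
        g = ["A", "A", "B", "B", "B"]
        chi2, df, _ = logrank_test(t, d, g)
        # O_A=1, E_A=2/5, V = d(n-d)/(n-1) * pA(1-pA) = 1*(2/5)(3/5)
        expected = (1 - 2 / 5) ** 2 / (2 / 5 * 3 / 5)
        assert chi2 == pytest.approx(expected)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        t = rng.integers(1, 60, 200)
        d = rng.random(200) < 0.6
        g = rng.integers(0, 3, 200)
        chi2, df, p = logrank_test(t, d, g)
        ref = multivariate_logrank_test(t, g, d)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)
        assert df == 2

    def test_single_group_raises(self):
        with pytest.raises(EstimationError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestWeeklyDistribution:
    def test_single_day_single_week(self):
        rec = _records([70, 70, 70], ["miscarriage"] * 3)
        hist = weekly_event_distribution(rec)
        assert hist["week"].tolist() == [10]
        assert hist["proportion"].tolist() == [1.0]

    def test_floor_week_binning(self):
        rec = _records([49, 56, 84], ["miscarriage"] * 3)
        assert weekly_event_distribution(rec)["week"].tolist() == [7, 8, 12]


class TestCumulativeIncidence:
    def test_no_events_zero(self):
        rec = _records([154] * 4, ["censored"] * 4)
        assert cumulative_incidence(rec)[0] == 0.0

    def test_no_censoring_reduces_to_crude_fraction(self):
        rec = _records([70, 80, 154, 154, 154], ["miscarriage", "miscarriage"] + ["censored"] * 3)
        est, lo, hi = cumulative_incidence(rec)
        assert est == pytest.approx(2 / 5)
        assert lo < est < hi

    def test_hand_product_limit_with_early_censor(self):
        # 10 women: events day 50 and 90, one censored day 40 (so 9 at
        # risk at the first event, 8 at the second)
        exits = [50, 90, 40] + [154] * 7
        events = ["miscarriage", "miscarriage", "censored"] + ["censored"] * 7
        est, _, _ = cumulative_incidence(_records(exits, events))
        expected = 1 - (1 - 1 / 9) * (1 - 1 / 8)
        assert est == pytest.approx(expected)


class TestModelRecovery:
    def test_constant_hazard_rate_recovery(self):
        """With constant weekly hazard h and week-resolution exits the
        person-week rate estimator recovers 1000·h (discrete identity)."""
        h, n, rng = 0.01, 20_000, np.random.default_rng(31)
        weeks = np.where(
            rng.random((n, 22)) < h, 1, 0
        )
        hit = weeks.any(axis=1)
        week = np.where(hit, weeks.argmax(axis=1) + 1, 22)
        rec = _records(7 * week, np.where(hit, "miscarriage", "censored"))
        est = incidence_rate(rec)
        se = 1000 * np.sqrt(est.n_events) / est.person_weeks
        assert abs(est.rate_per_1000pw - 1000 * h) < 3 * se

    def test_age_gradient_rate_ratios(self, big_pipeline):
        """Stratified all-loss rates recover the configured age-band hazard
        multipliers (closed-form crude ratios equal the multipliers to
        within ~0.3%)."""
        cfg, episodes, truth, pool_ids, covariates, records = big_pipeline
        rates = {}
        for band in ("<30", "30-34", "35-39", ">=40"):
            sub = records[records["age_band"] == band]
            n_events = (sub["outcome_class"] == "pregnancy_loss").sum()
            pw = sub["exit_day"].sum() / 7
            rates[band] = n_events / pw
        for band, mult in cfg.age_hazard_multipliers.items():
            ratio = rates[band] / rates["<30"]
            assert ratio == pytest.approx(mult, rel=0.10), band

    def test_week_share_matches_generator_closed_form(self, big_pipeline):
        """Weeks 7-12 share of miscarriages matches the hazard-implied
        closed form (~2/3 of losses at the default calibration)."""
        cfg, episodes, truth, pool_ids, covariates, records = big_pipeline
        recorded = records[records["lmp_source"] == "recorded"]
        hist = weekly_event_distribution(recorded)
        share = hist.loc[hist["week"].between(7, 12), "proportion"].sum()
        # closed form, mixed over age bands
        hz = np.asarray(cfg.baseline_weekly_hazard)
        s = cfg.hazard_scale()
        num = den = 0.0
        for band, pi in cfg.age_distribution.items():
            p = 1 - (1 - hz) ** (s * cfg.age_hazard_multipliers[band])
            surv = np.concatenate([[1.0], np.cumprod(1 - p)[:-1]])
            f = pi * p * surv
            weeks = np.arange(4, 23)
            num += f[(weeks >= 7) & (weeks <= 12)].sum()
            den += f.sum()
        expected = num / den
        n_events = hist["n"].sum()
        se = np.sqrt(expected * (1 - expected) / n_events)
        assert abs(share - expected) < 3 * se
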