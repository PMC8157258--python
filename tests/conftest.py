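import numpy as np
import pytest

from miscohort import SimConfig, generate_cohort, build_cohort
from miscohort.cox import ascertain_covariates
from miscohort.followup import build_followup
from miscohort.loss_classifier import classify_losses, confirmed_pool


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic cohort, n = 10,000."""
    cfg = SimConfig(n_women=10_000, seed=1)
    events, rx, women, truth = generate_cohort(cfg)
    return cfg, events, rx, women, truth


@pytest.fixture(scope="session")
def default_cohort(default_dataset):
    _, events, _, women, _ = default_dataset
    episodes, exclusions = build_cohort(events, women)
    return episodes, exclusions


@pytest.fixture(scope="session")
def big_pipeline():
    """n = 50,000 end-to-end run (episodes, pool, follow-up, covariates)."""
    cfg = SimConfig(n_women=50_000, seed=101)
    events, rx, women, truth = generate_cohort(cfg)
    episodes, _ = build_cohort(events, women)
    classified = classify_losses(episodes)
    pool_ids, ppvs, decisions = confirmed_pool(
        classified, truth, cfg.review_n, np.random.default_rng(102)
    )
    covariates = ascertain_covariates(episodes, events, rx, women)
    records = build_followup(episodes, pool_ids, women)
    return cfg, episodes, truth, pool_ids, covariates, records
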