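import numpy as np
import pandas as pd
import pytest

import beliefupdate as bu


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-like simulated cohort (18+18, 45 events), seed 7."""
    cfg = bu.paper_like_config(seed=7)
    participants, trials = bu.generate_cohort(cfg)
    return cfg, participants, trials


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    cfg, participants, trials = default_cohort
    classified = bu.classify_trials(trials)
    summaries = bu.summarize_participants(classified)
    table = bu.build_analysis_table(summaries, participants)
    return cfg, participants, classified, summaries, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_summary_table(rng, n1, n2):
    """Random per-participant 2x2 table for oracle comparisons."""
    n = n1 + n2
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "age_group": ["young"] * n1 + ["older"] * n2,
            "mean_update_desirable": rng.normal(5.0, 2.0, n),
            "mean_update_undesirable": rng.normal(2.0, 2.0, n),
        }
    )
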