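import numpy as np
import pandas as pd
import pytest

from hatchrank.simulate import SyntheticConfig, generate_dataset, simulate_latent_sequence


def random_sequence(n_events, n_individuals=6, seed=0):
    """Arbitrary (non-latent) winner/loser sequence for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    start = pd.Timestamp("2020-01-01")
    for e in range(n_events):
        i, j = rng.choice(n_individuals, size=2, replace=False)
        rows.append(
            {
                "date": start + pd.Timedelta(days=int(e // 5)),
                "group": "X",
                "winner": int(i) + 1,
                "loser": int(j) + 1,
                "behavior": ["HB", "M", "TB"][int(rng.integers(3))],
            }
        )
    df = pd.DataFrame(rows)
    df["seq_index"] = np.arange(n_events)
    return df


@pytest.fixture(scope="session")
def latent_seq():
    return simulate_latent_sequence(400, 6, k_true=20, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact but fully structured synthetic study (3 groups)."""
    cfg = SyntheticConfig(seed=42, n_months=3, events_per_session_mean=4.0)
    cohort, interactions, biometrics = generate_dataset(cfg)
    return cfg, cohort, interactions, biometrics


@pytest.fixture(scope="session")
def default_dataset():
    """The generator at its study-condition defaults (7 months, 3 groups)."""
    cfg = SyntheticConfig(seed=7)
    cohort, interactions, biometrics = generate_dataset(cfg)
    return cfg, cohort, interactions, biometrics
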