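import numpy as np
import pandas as pd
import pytest

import soilmerge as sm


@pytest.fixture(scope="session")
def default_config():
    """Default scenario: the emulated study conditions."""
    return sm.ScenarioConfig(seed=7)


@pytest.fixture(scope="session")
def coalescence(default_config):
    """Full phase-II dataset: SC/LC/SynCom controls plus both mergers."""
    return sm.generate_coalescence_dataset(default_config)


@pytest.fixture
def small_counts():
    return pd.DataFrame(
        [[1, 1, 2], [5, 0, 0], [3, 4, 3]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["a1", "a2", "a3"],
    )


@pytest.fixture
def small_taxonomy():
    return pd.DataFrame(
        {
            "genus": ["G1", "G1", "G2"],
            "phylum": ["P1", "P1", "P2"],
        },
        index=pd.Index(["a1", "a2", "a3"], name="asv_id"),
    )


def make_metadata(conditions, n_replicates=4, days=(0, 3)):
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for day in days:
                rows.append((f"{cond}.r{rep}.d{day:g}", cond, rep, float(day)))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "day"])
    return df.set_index("sample_id")


@pytest.fixture
def two_condition_metadata():
    return make_metadata(["A", "B"])


def random_counts(rng, n_samples=5, n_taxa=8, high=50):
    counts = rng.integers(0, high, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # no empty samples
    return pd.DataFrame(
        counts,
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"),
        columns=[f"t{j}" for j in range(n_taxa)],
    )
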