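import numpy as np
import pytest

from methage.synthetic_data import (
    SimulationConfig,
    simulate_counts,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def genome(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def counts_truth(genome, default_config):
    return simulate_counts(genome, default_config)


@pytest.fixture(scope="session")
def dataset(counts_truth):
    return counts_truth[0]


@pytest.fixture(scope="session")
def truth(counts_truth):
    return counts_truth[1]


def make_site_results(rows):
    """Build a per-CpG result table from (chrom, pos, delta, p) tuples."""
    import pandas as pd

    df = pd.DataFrame(rows, columns=["chrom", "pos", "delta", "p_value"])
    df["mean_young"] = 50.0
    df["mean_apa"] = 50.0 + df.delta
    df["significant"] = df.p_value <= 0.05
    df["direction"] = np.where(
        ~df.significant, "none", np.where(df.delta > 0, "hyper",
                                          np.where(df.delta < 0, "hypo", "none"))
    )
    return df[
        ["chrom", "pos", "mean_young", "mean_apa", "delta", "p_value",
         "significant", "direction"]
    ]
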