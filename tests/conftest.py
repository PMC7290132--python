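import numpy as np
import pandas as pd
import pytest

from biofilmnet import preprocess
from biofilmnet.simulate import SimulationConfig, generate_community


@pytest.fixture(scope="session")
def small_community():
    """One modest synthetic community shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=22, n_otus=300, depth_mean=3000, depth_sd=300, seed=11
    )
    return generate_community(cfg)


@pytest.fixture(scope="session")
def rel_table(small_community):
    table, _, _, _ = small_community
    return preprocess.relative_abundance(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_counts():
    """Hand-written 3-sample x 4-OTU table."""
    return pd.DataFrame(
        [[2, 3, 5, 0], [1, 0, 0, 9], [4, 4, 4, 4]],
        index=["A", "B", "C"],
        columns=["o1", "o2", "o3", "o4"],
    )
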