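import numpy as np
import pandas as pd
import pytest

from necmethylome import SimulationConfig, simulate_dataset


def make_samples(n_ctrl, n_nec, tissue="colon"):
    rows = [(f"{tissue}_ctrl_{i:02d}", tissue, "non-NEC") for i in range(n_ctrl)]
    rows += [(f"{tissue}_nec_{i:02d}", tissue, "NEC") for i in range(n_nec)]
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "condition"])


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cpg=5000,
        n_genes=100,
        genome_length=5_000_000,
        n_samples_per_group=4,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
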