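import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mindwander.simulate import SimConfig, simulate_dataset
from mindwander.trials import filter_and_flag
from mindwander.validation import dataset_edge_matrix, recovery_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """A fast null dataset: 12 regions, 4 runs, no planted signal."""
    return SimConfig(n_regions=12, n_runs=4, p_distracted=0.1, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    runs, events, gt, atlas = simulate_dataset(small_config)
    return runs, filter_and_flag(events), gt, atlas


@pytest.fixture(scope="session")
def recovery_dataset():
    """High-gain planted-edge dataset shared by CPM-level tests."""
    cfg = recovery_config(11)
    X, y, kept, atlas, gt, runs = dataset_edge_matrix(cfg)
    return cfg, X, y, kept, atlas, gt
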