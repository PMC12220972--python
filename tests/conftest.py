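import numpy as np
import pandas as pd
import pytest

from clonotrace import SimConfig, simulate_dataset, simulate_reads


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_patients=2,
        cells_per_compartment={"blood": 400, "tumor": 150, "NAT": 50},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cells, adata, truth = simulate_dataset(small_config)
    return cells, adata, truth


@pytest.fixture(scope="session")
def small_calls(small_config, small_dataset):
    cells, _, truth = small_dataset
    return simulate_reads(cells, truth, small_config)


@pytest.fixture(scope="session")
def noiseless_calls(small_config, small_dataset):
    cells, _, truth = small_dataset
    cfg = small_config.with_(tie_rate=0.0, chain_dropout=0.0, minor_call_rate=0.0)
    return simulate_reads(cells, truth, cfg)


@pytest.fixture(scope="session")
def labeled(small_dataset, noiseless_calls):
    from clonotrace import run_pipeline

    cells, _, _ = small_dataset
    return run_pipeline(cells, noiseless_calls)
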