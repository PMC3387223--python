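import numpy as np
import pandas as pd
import pytest

from lungmeth import dataio, differential, normalization
from lungmeth.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated study shared across the suite."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_sheet(default_dataset):
    return dataio.drop_duplicate_replicates(default_dataset.sheet)


@pytest.fixture(scope="session")
def default_qn(default_dataset, default_sheet):
    beta = default_dataset.beta[list(default_sheet.index)]
    return normalization.quantile_normalize(beta)


@pytest.fixture(scope="session")
def default_records(default_dataset, default_sheet, default_qn):
    stats = differential.moderated_t_test(
        default_qn, default_sheet["tissue"], "tumor", "normal"
    )
    return differential.call_differential(stats, manifest=default_dataset.manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_beta():
    return pd.DataFrame(
        np.array([[0.1, 0.2, 0.4, 0.5], [0.3, 0.3, 0.3, 0.3], [0.9, 0.8, 0.1, 0.2]]),
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2", "s3", "s4"],
    )
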