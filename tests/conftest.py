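import numpy as np
import pandas as pd
import pytest

from evmir.matrix import CountMatrix
from evmir.synthetic import SimParams, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    return simulate_counts(SimParams(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast dataset (500 miRNAs, two groups) for unit tests."""
    params = SimParams(n_mirnas=500, group_sizes={"CIS": 8, "HealthCtl": 8},
                       n_cis_down=3, n_rrms_up=0, n_shared_up=0, n_shared_down=0,
                       library_size_mean=5e5, seed=5)
    return simulate_counts(params)


def make_counts(values, groups, mirna_ids=None, sample_ids=None, **meta_cols):
    values = np.asarray(values)
    n, m = values.shape
    mirna_ids = mirna_ids or [f"miR-{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    meta = pd.DataFrame({"group": groups, **meta_cols},
                        index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(pd.DataFrame(values, index=mirna_ids, columns=sample_ids), meta)


@pytest.fixture
def toy_counts():
    return make_counts
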