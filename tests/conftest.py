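import numpy as np
import pandas as pd
import pytest

from coexsurv import synthdata


@pytest.fixture(scope="session")
def small_study():
    """A small planted-module cohort reused across tests: 3 modules
    (100/70/40 genes) + background, 200 samples, protective first module."""
    expr, clin, truth = synthdata.simulate_study(
        n_genes=400, n_samples=200, module_sizes=(100, 70, 40),
        loading_range=(0.5, 0.9), noise_sd=0.5,
        module_log_hr={"m1": float(np.log(0.6))}, censor_fraction=0.5,
        subtype_counts=(10, 3, 55, 65, 4), seed=42)
    return expr, clin, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n):
    """A valid random adjacency: symmetric, entries in [0,1], unit diag."""
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def adjacency_frame(a):
    genes = [f"g{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=genes, columns=genes)
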