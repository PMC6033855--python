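import numpy as np
import pandas as pd
import pytest

from ascabc.abc_core import SimulationTable
from ascabc.demography import ParameterPrior, PriorSet
from ascabc.io_cli import generate_toy_loci, generate_toy_manifest
from ascabc.pipeline import two_population_toy_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_loci():
    return generate_toy_loci(5, length=5000)


@pytest.fixture(scope="session")
def toy_manifest(toy_loci):
    return generate_toy_manifest(toy_loci, 4.0, seed=99, min_snps=1)


@pytest.fixture(scope="session")
def toy_spec():
    return two_population_toy_spec()


def make_linear_table(n_rows: int, seed: int, noise: float = 0.05):
    """Synthetic linear-Gaussian SimulationTable: two uniform parameters,
    statistics that are noisy linear functions of them.  Cheap stand-in for
    real simulations when testing the ABC machinery itself."""
    rng = np.random.default_rng(seed)
    priors = PriorSet([
        ParameterPrior("alpha", "uniform", 0.0, 1.0),
        ParameterPrior("beta", "uniform", -1.0, 1.0),
    ])
    params = pd.DataFrame({
        "alpha": rng.uniform(0, 1, n_rows),
        "beta": rng.uniform(-1, 1, n_rows),
    })
    A = np.array([[1.0, 0.5], [-0.3, 1.0], [0.8, -0.8], [0.2, 0.1]])
    X = params.to_numpy() @ A.T + noise * rng.standard_normal((n_rows, 4))
    stats = pd.DataFrame(X, columns=[f"s{j}" for j in range(4)])
    table = SimulationTable(params, stats, np.arange(n_rows), model_kind="linear_toy")
    return table, priors


@pytest.fixture
def linear_table():
    return make_linear_table(3000, seed=7)
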