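import numpy as np
import pandas as pd
import pytest

from mirnapipe import SimDesign, generate_reference, simulate_counts


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(
        n_mirna=20,
        group_sizes=(3, 3, 4),
        lib_size_range=(2e3, 3e3),
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_design):
    return generate_reference(small_design)


@pytest.fixture(scope="session")
def small_truth(small_design, small_reference):
    truth, pheno = simulate_counts(small_design, small_reference)
    return truth, pheno


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_counts(rng):
    """Moderate random NB count matrix with unequal libraries."""
    mu = np.exp(rng.uniform(0, 7, 150))
    libs = rng.uniform(0.5, 2.0, 6)
    counts = rng.negative_binomial(5, 5 / (5 + np.outer(mu, libs)))
    return pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(150)],
        columns=[f"s{j}" for j in range(6)],
    )
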