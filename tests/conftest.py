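import numpy as np
import pytest

from bcscea import (
    LifeTable,
    default_parameters,
    generate_lifetable,
    run_all,
    run_psa,
)


@pytest.fixture()
def params():
    """A fresh base-case parameter set (safe to mutate)."""
    return default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    """The packaged synthetic Gompertz-Makeham mortality schedule."""
    return generate_lifetable()


@pytest.fixture(scope="session")
def zero_mortality():
    """A life table with no background mortality (isolates disease dynamics)."""
    ages = np.arange(0, 121)
    return LifeTable(ages=ages, q=np.zeros_like(ages, dtype=float))


@pytest.fixture(scope="session")
def base_results(lifetable):
    """Deterministic base-case results for all three strategies."""
    return run_all(default_parameters(), lifetable)


@pytest.fixture(scope="session")
def psa_result(lifetable):
    """One fixed-seed 1000-iteration PSA shared across tests."""
    return run_psa(default_parameters(), lifetable, n_iter=1000, seed=1)
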