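import numpy as np
import pytest

from mutorder import (CoalescentConfig, ErrorRates, GenotypeMatrix,
                      fixture_table1, get_prior)


@pytest.fixture(scope="session")
def table1() -> GenotypeMatrix:
    return fixture_table1()


@pytest.fixture(scope="session")
def default_errors() -> ErrorRates:
    return ErrorRates()


@pytest.fixture(scope="session")
def no_errors() -> ErrorRates:
    return ErrorRates(fd=0.0, ad=0.0, c=0.0)


@pytest.fixture(scope="session")
def toy_two_sites() -> GenotypeMatrix:
    """Seven cells at two sites; the carriers of x are a strict subset of
    the carriers of y, so y's mutation is ancestral to x's."""
    calls = np.array([
        [0, 0, 0, 0, 1, 1, 0],   # x
        [0, 0, 1, 1, 1, 1, 1],   # y
    ], dtype=np.int8)
    return GenotypeMatrix(["x", "y"], [f"s{i}" for i in range(1, 8)], calls)


@pytest.fixture(scope="session")
def small_prior():
    """Fast small-MC prior for 58-cell matrices in unit tests."""
    return get_prior(CoalescentConfig(58, 0.92, b_tree=60, b_mut=400, seed=5))


@pytest.fixture(scope="session")
def study_prior():
    """Prior at the real study's conditions (58 cells, alpha 0.92,
    full Monte-Carlo sizes); shared across the slow acceptance tests."""
    return get_prior(CoalescentConfig(58, 0.92, b_tree=1000, b_mut=10000,
                                      seed=1))
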