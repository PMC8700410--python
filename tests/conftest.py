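import numpy as np
import pytest

from neitl import NEITLParams, load_sample


@pytest.fixture(scope="session")
def pigs():
    return load_sample("guinea_pigs")


@pytest.fixture(scope="session")
def group1():
    return load_sample("fluid_group1")


@pytest.fixture(scope="session")
def group2():
    return load_sample("fluid_group2")


@pytest.fixture(scope="session")
def pigs_ml(pigs):
    from neitl import fit_mle

    return fit_mle(pigs)


@pytest.fixture(scope="session")
def group_fits(group1, group2):
    """(ML1, ML2, MPS1, MPS2) for the insulating-fluid groups."""
    from neitl import fit_mle, fit_mps

    f1, f2 = fit_mle(group1), fit_mle(group2)
    m1 = fit_mps(group1, ml_result=f1)
    m2 = fit_mps(group2, ml_result=f2)
    return f1, f2, m1, m2


@pytest.fixture(scope="session")
def param_grid():
    """A spread of parameter pairs covering light and heavy tails."""
    return [
        NEITLParams(0.5, 0.5),
        NEITLParams(0.5, 3.0),
        NEITLParams(3.0, 0.5),
        NEITLParams(3.0, 3.0),
        NEITLParams(1.0, 2.0),
        NEITLParams(7.0, 2.0),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
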