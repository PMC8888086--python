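import numpy as np
import pytest

from pmlindley import PML, load_dataset

# the 4x4 parameter grid used for normalisation / stability checks
PARAM_GRID = [(a, t) for a in (0.5, 1.0, 2.0, 5.0) for t in (0.5, 1.0, 2.0, 5.0)]


@pytest.fixture(scope="session")
def covid():
    return load_dataset("covid_moldova").values


@pytest.fixture(scope="session")
def jute10():
    return load_dataset("jute_gauge10").values


@pytest.fixture(scope="session")
def jute20():
    return load_dataset("jute_gauge20").values


@pytest.fixture(scope="session")
def bank_a():
    return load_dataset("bank_a").values


@pytest.fixture(scope="session")
def bank_b():
    return load_dataset("bank_b").values


@pytest.fixture(scope="session")
def sim_sample():
    """A moderately sized sample from PML(2, 0.5), fixed seed."""
    return PML(2.0, 0.5).rvs(300, seed=20220222)


def quad_moment(dist: PML, r: float, lo: float = 0.0, hi: float = np.inf) -> float:
    """Quadrature oracle for integrals of x^r against the density."""
    from scipy import integrate

    val, _ = integrate.quad(lambda x: x**r * dist.pdf(x), lo, hi, limit=200)
    return val
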