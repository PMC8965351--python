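import numpy as np
import pytest

from se2rec import BankParams, dual_bank, gabor_bank

# reference parameter set used by the full-size checks
STUDY_N, STUDY_M, STUDY_S, STUDY_P, STUDY_R = 512, 12, 51.0, 170.0, 252.0


@pytest.fixture(scope="session")
def study_params():
    return BankParams(STUDY_N, STUDY_M, STUDY_S, STUDY_P)


@pytest.fixture(scope="session")
def study_bank(study_params):
    return gabor_bank(study_params)


@pytest.fixture(scope="session")
def study_dual(study_bank):
    return dual_bank(study_bank, STUDY_R)


@pytest.fixture(scope="session")
def small_params():
    return BankParams(16, 4, 3.0, 5.0)


@pytest.fixture(scope="session")
def small_bank(small_params):
    return gabor_bank(small_params)


@pytest.fixture(scope="session")
def small_dual(small_bank):
    return dual_bank(small_bank, 7.0)


@pytest.fixture(scope="session")
def tiny_params():
    # n*n*m = 192: small enough for dense-matrix oracles
    return BankParams(8, 3, 1.5, 2.0)


@pytest.fixture(scope="session")
def tiny_bank(tiny_params):
    return gabor_bank(tiny_params)


@pytest.fixture(scope="session")
def tiny_dual(tiny_bank):
    return dual_bank(tiny_bank, 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_stack(rng, n, m):
    return rng.standard_normal((n, n, m)) + 1j * rng.standard_normal((n, n, m))


def random_bandlimited(rng, n, radius):
    """Real image with spectrum strictly inside the ball of ``radius``."""
    from se2rec import bandlimit

    return bandlimit(rng.standard_normal((n, n)), radius)
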