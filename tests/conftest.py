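import numpy as np
import pytest

from fatiguenet.data_model import DEFAULT_BANDS, default_montage
from fatiguenet.synthetic import StudyDesign, generate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture(scope="session")
def short_design():
    """A fast study design for plumbing tests (64 s sessions)."""
    return StudyDesign(n_per_cell=2, duration=64.0, seed=11)


@pytest.fixture(scope="session")
def hbo_session(short_design):
    """One short synthetic session with all three species."""
    return generate_session(short_design, "p01", "PVT", "L1", seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(rng, n):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.abs(rng.standard_normal((n, n)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
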