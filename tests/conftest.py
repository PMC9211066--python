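import numpy as np
import pytest

from graspdecode.simulate import RgmrrProtocol, SubjectModel, draw_subject, simulate_session


@pytest.fixture(scope="session")
def default_subject() -> SubjectModel:
    return draw_subject(np.random.default_rng(123), seed=2024)


@pytest.fixture(scope="session")
def short_session(default_subject):
    """Four-cycle class-2 session: enough structure, fast to build."""
    return simulate_session(RgmrrProtocol(n_cycles=4, grasp_class=2), default_subject)


@pytest.fixture(scope="session")
def full_session(default_subject):
    """One full 30-cycle session (class 3)."""
    return simulate_session(RgmrrProtocol(grasp_class=3), default_subject)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
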