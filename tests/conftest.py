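import numpy as np
import pytest

from cogstates.synthetic import SyntheticConfig, neutral_face_template


@pytest.fixture(scope="session")
def small_config():
    """Two-subject, one-minute cohort: enough for every pipeline stage."""
    return SyntheticConfig(n_subjects=2, session_duration=60.0, seed=42)


@pytest.fixture()
def template():
    return neutral_face_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
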