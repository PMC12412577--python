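import numpy as np
import pytest

from whiskdecode import synth as S


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_profile():
    return S.make_profile("P0", rng_seed=5)


@pytest.fixture(scope="session")
def subject_60s(default_profile):
    """One 60-s synthetic subject used by several round-trip tests."""
    return S.synthesize_subject(default_profile, 60.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two 40-s subjects: just enough data to exercise training paths."""
    return S.make_cohort(2, 40.0, base_seed=21, heterogeneity=0.3)
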