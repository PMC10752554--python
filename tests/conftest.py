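import numpy as np
import pytest

import mmndyn as m


@pytest.fixture(scope="session")
def study1_seq():
    return m.study1_sequence(seed=11)


@pytest.fixture(scope="session")
def study2_seq():
    return m.study2_sequence(seed=11)


@pytest.fixture(scope="session")
def recovery_sequences():
    """A small cohort of study-1 sequences for recovery-style tests."""
    return [m.study1_sequence(seed=i) for i in range(28)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
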