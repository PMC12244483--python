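import numpy as np
import pytest

from cardaxes.synthetic_cohort import synth_mesh, synth_qrs_loop


@pytest.fixture(scope="session")
def default_mesh():
    mesh, truth = synth_mesh(seed=11)
    return mesh, truth


@pytest.fixture(scope="session")
def default_loop():
    loop, truth = synth_qrs_loop(seed=7)
    return loop, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
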