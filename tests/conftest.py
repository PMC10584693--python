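import numpy as np
import pytest

from mitoscale import synth


@pytest.fixture(scope="session")
def cell_stack():
    """One rendered synthetic cell (12 planted nucleoids, 50 fL) reused
    across image-pipeline tests."""
    nuc, mito, mask, truth = synth.synthetic_cell_stack(
        seed=7, volume_fl=50.0, n_nucleoids=12
    )
    return nuc, mito, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
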