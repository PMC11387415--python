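import numpy as np
import pytest

from dominoarray.optics import OpticsConfig
from dominoarray.scenarios import generate_dataset


@pytest.fixture(scope="session")
def five_dataset():
    """One rendered five-trigger dataset shared across imaging/HMM tests."""
    return generate_dataset("five_trigger", seed=11, n_structures=20)


@pytest.fixture(scope="session")
def short_optics():
    """A small, fast acquisition geometry for targeted rendering tests."""
    return OpticsConfig(
        image_size=(64, 64),
        total_duration=300.0,
        n_fiducials=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
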