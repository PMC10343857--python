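import numpy as np
import pytest

from ir2dcos import generate_dataset
from ir2dcos.containers import LabeledSpectrumSet


@pytest.fixture(scope="session")
def small_dataset() -> LabeledSpectrumSet:
    """3 classes x 6 samples on a short grid; shared across fast tests."""
    return generate_dataset(
        3, 6, grid_spec={"start": 1800.0, "stop": 1000.0, "step": 8.0}, seed=42
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
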