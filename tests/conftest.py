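import numpy as np
import pytest

from emostroop.synthetic import GroundTruth, simulate_roi_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One default-calibration dataset at the study's group sizes."""
    return simulate_roi_dataset(seed=7)


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth()
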