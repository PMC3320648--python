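import numpy as np
import pytest

from naturalscan.synthgen import SynthConfig, synth_study


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study small enough for per-module tests."""
    return SynthConfig(
        n_subjects=3, n_timepoints=120, n_voxels=500, mask_shape=(10, 10, 5), seed=7
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(annotations, designs, datasets, truth) generated once per session."""
    return synth_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
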