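import numpy as np
import pytest

import senpai


@pytest.fixture(scope="session")
def suite():
    """Standard phantom battery, seed 0 (shared; treat as read-only)."""
    return senpai.standard_suite(0)


@pytest.fixture(scope="session")
def phantom_config():
    """Segmentation settings for the phantom noise conditions."""
    return senpai.PipelineConfig(sigmas=[1.5], background_threshold=("percentile", 85.0),
                                 random_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
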