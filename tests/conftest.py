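import numpy as np
import pytest

from siren import DiscretizationConfig, ScoreConfig


@pytest.fixture
def default_disc() -> DiscretizationConfig:
    return DiscretizationConfig(num_bins=10, spline_order=3)


@pytest.fixture
def default_score() -> ScoreConfig:
    return ScoreConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250923)
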