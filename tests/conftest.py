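import numpy as np
import pytest

from coastmix import SourceDistribution, SyntheticDesign, TEFScenario


@pytest.fixture
def design():
    return SyntheticDesign(seed=7, n_sources_per_group=20, n_consumers=10)


@pytest.fixture
def four_sources():
    """Well-separated four-group layout with the standard group names."""
    return [
        SourceDistribution("terrestrial_plant", -25.0, 1.0, 5.0, 1.0, 42.0, 2.0),
        SourceDistribution("terrestrial_vertebrate", -21.0, 1.0, 8.0, 1.0, 43.0, 13.0),
        SourceDistribution("marine_invertebrate", -14.0, 1.0, 11.0, 1.0, 40.0, 10.0),
        SourceDistribution("marine_vertebrate", -13.0, 1.0, 16.0, 1.0, 44.0, 14.0),
    ]


@pytest.fixture
def tef():
    return TEFScenario("test", 3.0, 0.5, 6.0, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
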