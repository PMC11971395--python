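import numpy as np
import pytest

from axoasym import synthetic as syn


@pytest.fixture(scope="session")
def default_axoneme():
    """One noiseless untilted axoneme image with its doublet centres."""
    spec = syn.SyntheticAxonemeSpec()
    images, centres = syn.generate_axoneme_stack(spec, 1)
    return spec, images[0], centres[0]


@pytest.fixture(scope="session")
def noiseless_beat():
    spec = syn.SyntheticBeatSpec(noise_sd=0.0)
    series, truth = syn.generate_beat_series(spec)
    return spec, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
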