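import numpy as np
import pytest

from finchcall import (
    RenditionJitter,
    example_motif_spec,
    template_from_motif_spec,
)

#: Reduced rate for tests that only need envelope-scale structure.
TEST_RATE = 22_050


@pytest.fixture(scope="session")
def motif_spec():
    return example_motif_spec(n_syllables=4)


@pytest.fixture(scope="session")
def jitter():
    return RenditionJitter(duration_cv=0.05, f0_cv=0.02, level_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def template(motif_spec, jitter):
    """Four-syllable motif template with a 4-rendition bank at 22.05 kHz."""
    return template_from_motif_spec(motif_spec, jitter, n_renditions=4, rate=TEST_RATE)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
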