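import numpy as np
import pytest

from songphys import synth


@pytest.fixture(scope="session")
def default_model():
    return synth.make_default_song_model(1)


@pytest.fixture(scope="session")
def default_bouts(default_model):
    """A modest seeded batch of default-model bouts shared across tests."""
    waveforms, annotations, truth = synth.synthesize_bouts(
        default_model, n_bouts=30, seed=42
    )
    return waveforms, annotations, truth


from songphys.recovery import motif_model, single_syllable_model  # noqa: E402,F401


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
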