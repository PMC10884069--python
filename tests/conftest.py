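import numpy as np
import pytest

from covmap import (ChannelInfo, Recording, generate_microstate_sequence,
                    render_scalp_eeg, synthetic_template_set)


@pytest.fixture(scope="session")
def templates():
    return synthetic_template_set()


@pytest.fixture(scope="session")
def sequence_60s():
    """60 s, 500 Hz, 7-class ground-truth microstate sequence."""
    return generate_microstate_sequence(30000, 500.0, 0.08, 7, seed=11)


@pytest.fixture(scope="session")
def scalp_noiseless(sequence_60s, templates):
    return render_scalp_eeg(sequence_60s, templates, 0.0, seed=12)


@pytest.fixture()
def small_recording():
    rng = np.random.default_rng(0)
    chans = [ChannelInfo(f"ch{i}", "scalp", "scalp") for i in range(4)]
    return Recording(rng.normal(0.0, 30.0, (4, 5120)), 512.0, chans)
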