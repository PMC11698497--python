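import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

FS = 20_000.0


@pytest.fixture(scope="session")
def pair_recording():
    """One 20 s two-fish recording with 15 planted chirps (seed 7)."""
    from chirplab import synth

    rng = np.random.default_rng(7)
    f1 = synth.sample_fish("male", rng, id="1")
    f2 = synth.sample_fish("female", rng, id="2")
    rec, events = synth.simulate_pair_recording(
        f1, f2, duration=20.0, n_chirps=15, rng=rng)
    return rec, events, {"1": f1.eodf, "2": f2.eodf}
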