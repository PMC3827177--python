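import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from erdvoice.melody import Melody, generate_melody
from erdvoice.synth import synth_triangle


@pytest.fixture(scope="session")
def female_melody():
    return generate_melody(42, "female")


@pytest.fixture(scope="session")
def triangle_clip(female_melody):
    return synth_triangle(female_melody)


@pytest.fixture(scope="session")
def fixed_melody():
    """A known melody: G3, A3, B3, A3, G3 (semitones re C4)."""
    return Melody(pitches=(-5, -3, -1, -3, -5), tessitura="female", id="fix")


def make_gaussian_epochs(n_trials=20, n_ch=4, n_samp=512, sd=10.0, seed=0):
    """Homogeneous Gaussian epochs for rejection tests."""
    from erdvoice.recording import EpochSet

    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, sd, (n_trials, n_ch, n_samp))
    return EpochSet(
        data=data,
        ch_names=[f"ch{i}" for i in range(n_ch)],
        sfreq=512.0,
        times=np.arange(n_samp) / 512.0 - 0.5,
        conditions=["vocal" if i % 2 else "nonvocal" for i in range(n_trials)],
    )
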