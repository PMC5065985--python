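import numpy as np
import pytest

from hfnet.synthetic import OscillatorSpec, gen_coupled_oscillators
from hfnet.wavelet import recording_phases


@pytest.fixture(scope="session")
def locked_pair_recording():
    """Two noiseless channels at 10 Hz, b locked to a with b leading by pi/8."""
    specs = [
        OscillatorSpec("a", 10.0),
        OscillatorSpec("b", 10.0, coupled_to=("a", 10.0, 1, 1, np.pi / 8)),
    ]
    return gen_coupled_oscillators(specs, fs=250.0, duration=10.0, seed=0)


@pytest.fixture(scope="session")
def locked_pair_phases(locked_pair_recording):
    return recording_phases(locked_pair_recording, freqs=[10.0])


def random_digraph(rng, n=None, density=0.4):
    """Random weighted digraph with zero diagonal, weights in (0, 1]."""
    if n is None:
        n = int(rng.integers(4, 11))
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(w, 0.0)
    return w
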