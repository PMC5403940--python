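import numpy as np
import pytest

import spidock as sd


@pytest.fixture(scope="session")
def toy_complex():
    return sd.make_toy_complex(50, 30, seed=1)


@pytest.fixture(scope="session")
def small_detector():
    # same q range as the default geometry at a quarter of the pixel count
    return sd.BeamDetector(pixel_size=0.9, n_fast=64, n_slow=64)


@pytest.fixture(scope="session")
def small_qmap(small_detector):
    return sd.build_qmap(small_detector)


@pytest.fixture(scope="session")
def tiny_qmap():
    return sd.build_qmap(sd.BeamDetector(pixel_size=1.8, n_fast=32, n_slow=32))


@pytest.fixture(scope="session")
def scaled_patterns(toy_complex, small_qmap):
    """20 noise-free photon-scaled patterns of the toy native at random
    subspace orientations."""
    oris = sd.sample_orientations(
        20, bounds=((-22.5, 22.5),) * 3, seed=3)
    ps = sd.simulate_set(toy_complex.combined, oris, small_qmap)
    return sd.scale_to_photons(ps, d_target=4.0)
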