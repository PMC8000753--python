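import numpy as np
import pytest

from osteofem.geometry import ScaffoldParams, build_spike_layout
from osteofem.synth import VolumeSpec, generate_trabecular_volume


@pytest.fixture(scope="session")
def default_layout():
    return build_spike_layout(ScaffoldParams())


@pytest.fixture(scope="session")
def single_spike_layout():
    return build_spike_layout(ScaffoldParams(n_rings=0))


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 trabecular phantom with planted pores, speckles and noise."""
    spec = VolumeSpec(shape=(64, 64, 64), seed=3)
    volume, bone = generate_trabecular_volume(spec)
    return spec, volume, bone


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom without planted objects (exact ground truth)."""
    spec = VolumeSpec(shape=(64, 64, 64), noise_sd=0.0, n_canals=0,
                      n_lacunae=0, n_speckles=0, seed=11)
    volume, bone = generate_trabecular_volume(spec)
    return spec, volume, bone
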