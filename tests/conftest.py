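import numpy as np
import pytest

from jmoct import Layer, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def identity_phantom():
    """Noiseless, non-birefringent, non-attenuating single layer."""
    spec = PhantomSpec(layers=[Layer(thickness=24)], lateral_size=12,
                       axial_size=24, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def scrambled_phantom():
    """Fully polarization-scrambling layer (isotropic random states)."""
    spec = PhantomSpec(layers=[Layer(thickness=40, scrambling=1.0)],
                       lateral_size=300, axial_size=40, seed=5)
    return generate_phantom(spec)
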