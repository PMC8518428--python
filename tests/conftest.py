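import numpy as np
import pytest

from livernav.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-size phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom for pipeline tests."""
    return generate_phantom(PhantomSpec(shape=(40, 40, 40), spacing_mm=4.0, seed=2))


def random_mask_pair(rng, shape, spacing=(1.0, 1.0, 1.0)):
    from livernav.volume import Mask

    a = (rng.random(shape) > 0.7).astype(np.uint8)
    b = (rng.random(shape) > 0.7).astype(np.uint8)
    return Mask(a, spacing), Mask(b, spacing)
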