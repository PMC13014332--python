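import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cestpipe import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom: same physics, quarter-size grid."""
    base = dict(
        grid_shape=(24, 24, 2),
        brain_center=(11.5, 11.5, 0.5),
        brain_semiaxes=(10.0, 9.0, 4.0),
        tumor_center=(8.0, 9.0, 0.5),
        tumor_semiaxes=(3.5, 2.5, 1.2),
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_noisy_phantom():
    return generate_phantom(small_spec(noise_sigma=0.005, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
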