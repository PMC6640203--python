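import numpy as np
import pytest

from swarmclust.energy_backends import LennardJonesBackend, MorseBackend

# Frozen reference minima, computed with the multi-start oracle
# (io_bench.reference_minimum / enumerate_minima, 300-400 starts, seeds 0/1)
# before the search code was tuned; they match the standard published
# Lennard-Jones cluster values.
LJ_REFERENCE = {
    3: -3.0,
    4: -6.0,
    5: -9.10385242,
    6: -12.71206226,
}
# the two (and only two) LJ6 compact-cluster funnels
LJ6_FUNNELS = (-12.71206226, -12.30292754)


@pytest.fixture(scope="session")
def lj_backend():
    return LennardJonesBackend()


@pytest.fixture(scope="session")
def morse_backend():
    return MorseBackend()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a uniformly random rotation plus translation to (n,3) coords."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-5, 5, size=3)
    return coords @ q.T + t
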