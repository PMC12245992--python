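import numpy as np
import pytest

from vadsim import default_anatomy
from vadsim.reporting import run_sweep


def random_isochoric_states(n, seed, spread=0.2):
    """Seeded random unimodular deformation gradients with unit fibers."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        det = np.linalg.det(F)
        if det <= 0.05:  # reject the rare near-singular draw
            continue
        F = F / det ** (1.0 / 3.0)
        N = rng.standard_normal(3)
        N /= np.linalg.norm(N)
        out.append((F, N))
    return out


@pytest.fixture(scope="session")
def anatomy():
    return default_anatomy()


@pytest.fixture(scope="session")
def sweep_results(anatomy):
    """Full 12-scenario sweep on the default anatomy at dt = 1 s."""
    return run_sweep(anatomy)
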