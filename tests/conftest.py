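import numpy as np
import pytest

from cgmemsim import default_forcefield


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cluster(rng, n, spread=2.0, min_sep=0.42):
    """n random points with a minimum separation (avoids LJ blow-ups)."""
    pts = [rng.uniform(0, spread, 3)]
    while len(pts) < n:
        p = rng.uniform(0, spread, 3)
        if min(np.linalg.norm(p - q) for q in pts) > min_sep:
            pts.append(p)
    return np.array(pts)
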