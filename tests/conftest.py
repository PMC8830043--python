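import numpy as np
import pytest

import cortexmd as cm


@pytest.fixture(scope="session")
def sphere_pair():
    """Subdivision-3 phantom pair: white r=50 mm, 3 mm ribbon (642 vertices)."""
    spec = cm.PhantomSpec(icosphere_subdivisions=3)
    return spec, cm.make_surface_pair(spec)


@pytest.fixture(scope="session")
def mesh642(sphere_pair):
    return sphere_pair[1].white


@pytest.fixture(scope="session")
def protocol12():
    """1 b=0 volume + 12 well-spread b=1000 directions."""
    rng = np.random.default_rng(42)
    g = rng.standard_normal((12, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    bvals = np.r_[0.0, np.full(12, 1000.0)]
    bvecs = np.vstack([[0.0, 0.0, 0.0], g])
    return cm.DiffusionProtocol(bvals, bvecs)


@pytest.fixture(scope="session")
def protocol30():
    rng = np.random.default_rng(7)
    g = rng.standard_normal((30, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return cm.DiffusionProtocol(np.r_[0.0, np.full(30, 1000.0)], np.vstack([[0, 0, 0], g]))
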