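import numpy as np
import pytest

import dimerdyn as dd


@pytest.fixture(scope="session")
def bundle():
    """Default ideal bundle: topology, coordinates, helix set."""
    return dd.build_ideal_bundle()


@pytest.fixture(scope="session")
def short_run(bundle):
    """Small drift-free simulated run with the default planted manifest."""
    topo, coords, hs = bundle
    manifest = dd.default_manifest(topo, coords, hs, seed=11)
    traj, log = dd.simulate_trajectory(topo, coords, manifest, 300, 100.0)
    return traj, log, manifest, hs


def random_rigid_transform(rng):
    q = rng.standard_normal((3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    trans = rng.uniform(-20, 20, 3)
    return rot, trans
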