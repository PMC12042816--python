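import numpy as np
import pytest

from mifkit import Molecule, SphericalGridSpec, build_frame, make_spherical_grid
from mifkit.fixtures import toy_ring_molecule


@pytest.fixture
def hexagon():
    """Regular benzene-like hexagon in the lab xy-plane, atom 0 on +x."""
    return toy_ring_molecule(6, 1.39)


@pytest.fixture
def pyridine_like():
    """Six-membered ring with one nitrogen (no H at the N position)."""
    return toy_ring_molecule(6, 1.39, hetero={0: "N"})


@pytest.fixture
def hexagon_frame(hexagon):
    return build_frame(hexagon, range(6), u_atom=0)


@pytest.fixture
def tiny_grid():
    """Six-point spherical shell at 3.6 A (poles + 4-ring)."""
    return make_spherical_grid(SphericalGridSpec(3.6, 3.6, 0.2, 90.0, 90.0))


def random_ring(rng, n=6, radius=1.4):
    """A random non-degenerate planar ring rigidly placed in space."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return pts @ Q.T + rng.uniform(-5, 5, size=3), Q
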