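"""Shared fixtures: analytic meshes and synthetic phantoms.

Everything is generated programmatically; the six stock phantoms are
built once per session since several suites (and the acceptance checks)
share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from arguide.mesh import SurfaceMesh, make_box, make_icosphere
from arguide.phantom import PhantomSpec, default_phantom_specs, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def sphere30():
    """Icosphere of radius 30 mm, fine enough for area/volume oracles."""
    return make_icosphere(30.0, subdivisions=4)


@pytest.fixture(scope="session")
def plate():
    """Flat 16 x 16 x 3 mm plate (boolean-edit testbed)."""
    return make_box([16.0, 16.0, 3.0])


def grid_patch(half: float = 10.0, n: int = 21, z_fn=None) -> SurfaceMesh:
    """Open rectangular patch mesh in the z=0 plane (or lifted by z_fn)."""
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    Z = np.zeros_like(X) if z_fn is None else z_fn(X, Y)
    V = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, (i + 1) * n + j, i * n + j + 1, (i + 1) * n + j + 1
            F += [[a, b, d], [a, d, c]]
    return SurfaceMesh(V, np.array(F))


@pytest.fixture
def flat_patch():
    return grid_patch(10.0, 21)


@pytest.fixture(scope="session")
def small_phantom():
    """Cheap asymmetric phantom for unit tests (coarse grid, small dims)."""
    spec = PhantomSpec("TEST0001", (90.0, 70.0, 60.0), bone_kind="tube",
                       n_guide_fiducials=4, seed=7, pitch_mm=1.5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def stock_phantoms():
    """The six stock phantoms at their stated sizes (shared, ~5 s)."""
    return [generate_phantom(s) for s in default_phantom_specs()]
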