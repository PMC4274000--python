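import numpy as np
import pytest

import patchct as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geom():
    """8x8 image, 4 angles, wide detector — dense-oracle scale."""
    return pc.ProjectionGeometry(np.array([0.0, 45.0, 90.0, 135.0]), 14, 8)


@pytest.fixture(scope="session")
def dense_matrix(small_geom):
    """Forward operator assembled column-by-column from basis images."""
    cols = []
    for i in range(64):
        e = np.zeros(64)
        e[i] = 1.0
        cols.append(pc.forward_project(e.reshape(8, 8), small_geom).values.ravel())
    return np.stack(cols, axis=1)


@pytest.fixture(scope="session")
def small_dictionary(rng):
    """Well-conditioned random unit-norm dictionary, 4x4 patches, K=24."""
    atoms = np.random.default_rng(7).standard_normal((24, 16))
    atoms /= np.linalg.norm(atoms, axis=1, keepdims=True)
    return pc.Dictionary(atoms, m=4)


@pytest.fixture(scope="session")
def small_problem(small_dictionary):
    """16x16 tomography toy problem with an overlapping lattice."""
    lat = pc.build_lattice(16, 4, 2)
    core = pc.core_map(lat)
    geom = pc.ProjectionGeometry(np.arange(6) * 30.0, 24, 16)
    data_rng = np.random.default_rng(11)
    sino = pc.Sinogram(data_rng.standard_normal((6, 24)), geom)
    return lat, core, geom, sino
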