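import numpy as np
import pytest

from gqfold import (
    build_native_contacts,
    default_intermediate_spec,
    make_intermediate_ensemble,
    make_toy_quadruplex,
)


@pytest.fixture(scope="session")
def native():
    return make_toy_quadruplex()


@pytest.fixture(scope="session")
def contacts(native):
    return build_native_contacts(native)


@pytest.fixture(scope="session")
def small_ensemble(native):
    """300-frame synthetic intermediate ensemble (fast unit-test size)."""
    spec = default_intermediate_spec(seed=7)
    spec.n_frames = 300
    return spec, make_intermediate_ensemble(spec, native)


def random_rigid_motion(rng):
    """A uniform random rotation matrix and a translation vector."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-2, 2, 3)


def transform_structure(structure, rot, shift):
    out = structure.copy()
    for nt in out.nucleotides:
        for role in nt.atoms:
            nt.atoms[role] = rot @ nt.atoms[role] + shift
    if out.ions.size:
        out.ions = (rot @ out.ions.T).T + shift
    return out
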