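import numpy as np
import pytest

import ffguide as fg


@pytest.fixture(scope="session")
def fixture_molecules():
    """Ten embedded drug-like molecules (explicit H, deterministic)."""
    return fg.make_fixture_set(10, seed=1)


@pytest.fixture(scope="session")
def param_sets(fixture_molecules):
    return [fg.parameterize(m) for m in fixture_molecules]


@pytest.fixture(scope="session")
def small_molecule(fixture_molecules):
    """The smallest fixture — cheap enough for finite differences."""
    return min(fixture_molecules, key=lambda m: m.n_atoms)


@pytest.fixture()
def toy_pocket():
    return fg.make_toy_pocket("point_charges", seed=2)


def random_rigid_transform(rng):
    """A uniformly random rotation plus a translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = 5.0 * rng.standard_normal(3)
    return rot, shift
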