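import numpy as np
import pytest

from ribodyn import SyntheticSpec, make_reference, make_trajectory, select_atoms


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_residues=20,
        n_frames=200,
        correlation_blocks=(((8, 9, 10, 11), 0.8),),
        hbond_schedule=(((8, "N2"), (16, "O2"), 0.68),),
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return make_reference(small_spec)


@pytest.fixture(scope="session")
def small_trajectory(small_spec, small_reference):
    return make_trajectory(small_reference, small_spec)


@pytest.fixture(scope="session")
def c5_selection(small_reference):
    return select_atoms(small_reference, "C5'")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.normal(scale=10.0, size=3)
    return rot, shift
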