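import numpy as np
import pytest

from tmhc import synthetic
from tmhc.structure_io import ChainStructure, ResidueRecord


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_residue(
    rng: np.random.Generator, position: int = 1, n_extra: int = 3
) -> ResidueRecord:
    """A residue with N/CA/C/O/CB plus random extra side-chain atoms."""
    atoms = {}
    names = ["N", "CA", "C", "O", "CB"] + [f"X{k}" for k in range(n_extra)]
    for name in names:
        atoms[name] = rng.uniform(-8, 8, size=3)
    return ResidueRecord(position, "ALA", atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def two_helix_bundle():
    """Antiparallel two-helix bundle with contacts, fixed seed."""
    spec = synthetic.BundleSpec(
        n_helices=2, helix_length=18, inter_axis_distance=9.0, seed=11
    )
    return synthetic.make_bundle(spec)


@pytest.fixture(scope="session")
def study_dataset():
    """The default 10-chain study set (clean) with ground truth."""
    return synthetic.make_dataset(10, seed=0)
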