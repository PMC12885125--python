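import numpy as np
import pytest

from ensdock import Residue, Structure, SynthConfig, Trajectory


def straight_chain(n: int, spacing: float = 3.8, resnum0: int = 1) -> Structure:
    """Colinear Cα trace along x, used where distances must be hand-checkable."""
    residues = [
        Residue(resnum=resnum0 + i, chain="A", resname="GLY", ca=(i * spacing, 0.0, 0.0))
        for i in range(n)
    ]
    return Structure(id=f"line{n}", residues=residues)


def random_cloud(rng, n: int, scale: float = 5.0) -> np.ndarray:
    return rng.normal(scale=scale, size=(n, 3))


def random_rigid_motion(rng):
    """A uniform random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain10():
    return straight_chain(10)


@pytest.fixture
def small_cfg():
    return SynthConfig(seed=11, n_residues=30, n_frames=12)
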