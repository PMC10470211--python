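import numpy as np
import pytest

from carotenostruct import synthetic_data as synth


@pytest.fixture
def default_spec():
    return synth.SyntheticComplexSpec()


@pytest.fixture
def polyene(default_spec):
    return synth.make_polyene(default_spec)


@pytest.fixture
def shell_complex():
    """Two stacked polyenes with a small polar shell on two chains."""
    spec = synth.SyntheticComplexSpec(shell=[
        synth.ShellSpec("A", "SER", 2.8),
        synth.ShellSpec("A", "LYS", 3.9),
        synth.ShellSpec("B", "SER", 2.8, ligand_index=2),
        synth.ShellSpec("B", "LYS", 3.9, ligand_index=2),
    ])
    return synth.make_complex(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
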