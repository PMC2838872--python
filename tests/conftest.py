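import numpy as np
import pytest

from pocketkernel import Pocket, RigidMotion
from pocketkernel.synthetic import _random_quaternion_rotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_motion():
    def make(rng, tmax=10.0):
        return RigidMotion.from_matrix(
            _random_quaternion_rotation(rng), rng.uniform(-tmax, tmax, 3)
        )

    return make


@pytest.fixture
def random_pocket():
    def make(rng, n=20, scale=3.0, labeled=False):
        return Pocket(
            rng.normal(size=(n, 3)) * scale,
            labels=rng.choice([-0.5, -0.3, 0.0, 0.2, 0.4], n) if labeled else None,
        )

    return make


def write_toy_pdb(path, extra_lines=(), ligand_distances=(3.0, 5.2, 5.4, 9.0)):
    """A minimal PDB: one-atom ligand at origin, CA atoms at given distances."""

    def atom(serial, name, resname, chain, resseq, x, y, z,
             record="ATOM", altloc=" ", occ=1.0, element=None):
        element = element or name[0]
        return (
            f"{record:<6s}{serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )

    lines = []
    for i, d in enumerate(ligand_distances):
        lines.append(atom(i + 1, "CA", "GLY", "A", i + 1, d, 0.0, 0.0))
    lines.append(
        atom(90, "P", "LIG", "A", 99, 0.0, 0.0, 0.0, record="HETATM", element="P")
    )
    lines.extend(extra_lines)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_pdb(tmp_path):
    return write_toy_pdb(tmp_path / "toy.pdb")
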