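import numpy as np
import pytest

from specmap import synth
from specmap.structure import Atom, Chain, Residue, StructureModel


@pytest.fixture
def default_alignment():
    return synth.gen_labeled_alignment(seed=42)


@pytest.fixture
def alignment_truth():
    return synth.default_alignment_truth()


@pytest.fixture
def structure_truth():
    return synth.PlantedStructureTruth()


@pytest.fixture
def toy_complex(structure_truth):
    return synth.gen_toy_complex(n_residues=30, truth=structure_truth, seed=11)


@pytest.fixture
def two_mode_poses():
    return synth.gen_pose_set(seed=5)


def make_structure(residue_positions, ligand_positions=None, partner_positions=None):
    """Minimal single-atom-per-residue structure for geometry tests.

    residue_positions: list of (x, y, z) for chain C residues numbered 1..n.
    """
    chains = [Chain("C", [
        Residue("ALA", i + 1, atoms=[Atom("CA", "C", p)])
        for i, p in enumerate(residue_positions)])]
    roles = {"C": "accessory-C"}
    ligand = []
    if ligand_positions is not None:
        chains.append(Chain("L", [Residue(
            "LIG", 901, het=True,
            atoms=[Atom(f"C{j+1}", "C", p) for j, p in enumerate(ligand_positions)])]))
        ligand = [("L", 901)]
    if partner_positions is not None:
        chains.append(Chain("B", [
            Residue("GLY", 801 + j, atoms=[Atom("CA", "C", p)])
            for j, p in enumerate(partner_positions)]))
        roles["B"] = "partner-B"
    return StructureModel(chains=chains, roles=roles, ligand=ligand)


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
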