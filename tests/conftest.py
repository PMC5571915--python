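import numpy as np
import pytest

from dockint.fixtures import ToyComplexSpec, make_toy_complex
from dockint.structures import ResidueKey, StructureModel


def build_model(residue_positions, chain_id="A", names=None, radius=1.7,
                element="C", source_id="synthetic"):
    """StructureModel from a list of per-residue atom-coordinate lists."""
    coords, radii, elements, atom_names, atom_res = [], [], [], [], []
    residues = []
    for ridx, atoms in enumerate(residue_positions):
        name = (names[ridx] if names else "ALA")
        residues.append(ResidueKey(chain_id, ridx + 1, "", name))
        for aidx, xyz in enumerate(atoms):
            coords.append(xyz)
            radii.append(radius)
            elements.append(element)
            atom_names.append("CA" if aidx == 0 else f"CB")
            atom_res.append(ridx)
    return StructureModel(
        coords=np.array(coords, dtype=float),
        vdw_radii=np.array(radii),
        elements=np.array(elements),
        atom_names=np.array(atom_names),
        atom_residue=np.array(atom_res),
        residues=residues,
        source_id=source_id,
    )


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  element="C", altloc=" "):
    return (f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} "
            f"{chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def simple_pdb(n_chains=2, n_residues=5, n_atoms=4):
    """PDB text with n_chains x n_residues x n_atoms CA-like atoms."""
    lines = []
    serial = 0
    names = ["N", "CA", "C", "O", "CB", "CG"]
    for c in range(n_chains):
        chain = chr(ord("A") + c)
        for r in range(1, n_residues + 1):
            for a in range(n_atoms):
                serial += 1
                element = "N" if names[a] == "N" else (
                    "O" if names[a] == "O" else "C")
                lines.append(pdb_atom_line(
                    serial, names[a], "ALA", chain, r,
                    10.0 * c + 4.0 * r + a, 1.0, 1.0, element=element))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(ToyComplexSpec(seed=1))
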