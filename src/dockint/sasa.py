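"""Solvent-accessible surface area (Shrake-Rupley) and relative ASA.

The ASA of each atom is estimated by placing a quasi-uniform set of test
points on a sphere of radius ``r_vdw + probe`` around it and counting the
fraction not occluded by any neighbouring atom's expanded sphere.  Relative
ASA (rASA) divides the per-residue sum by a residue-type reference maximum
(the Tien et al. 2013 theoretical maxima), giving the dimensionless burial
measure used for the core / surface split at rASA = 0.1.

The point set is a deterministic Fibonacci spiral, so results are exactly
reproducible for a given ``n_points``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import ResidueKey, StructureModel

__all__ = [
    "MAX_ASA_TIEN_2013",
    "ASAProfile",
    "sphere_points",
    "atom_asa",
    "compute_asa",
    "relative_asa",
]

# Theoretical maximum ASA per residue type (A^2), Tien et al. 2013.
MAX_ASA_TIEN_2013: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
REFERENCE_TABLE_ID = "tien2013-theoretical"


@dataclass
class ASAProfile:
    """Per-residue absolute and relative solvent accessibility.

    ``residues`` fixes the ordering of ``asa`` and ``rasa``; ``source_id``
    records which structure the profile was computed on.
    """

    residues: list[ResidueKey]
    asa: np.ndarray            # A^2, per residue
    rasa: np.ndarray           # dimensionless
    atom_asa: np.ndarray       # A^2, per atom of the source structure
    probe_radius: float
    n_points: int
    reference_table_id: str = REFERENCE_TABLE_ID
    source_id: str = ""

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float)
        self.rasa = np.asarray(self.rasa, dtype=float)
        if np.any(self.asa < -1e-9) or np.any(self.rasa < -1e-9):
            raise ValueError("negative accessibility")

    def as_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residues, self.asa))

    def rasa_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residues, self.rasa))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral unit vectors, shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_asa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
             n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom exposed area (A^2) by the Shrake-Rupley point method."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    if n_atoms == 0:
        raise ValueError("structure has no atoms")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    expanded = radii + probe_radius
    pts = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    out = np.empty(n_atoms, dtype=float)
    for i in range(n_atoms):
        ri = expanded[i]
        # neighbours whose expanded sphere could occlude points on sphere i
        nbr = tree.query_ball_point(coords[i], ri + max_r)
        nbr = [j for j in nbr if j != i]
        test = coords[i] + ri * pts
        if nbr:
            nbr = np.asarray(nbr)
            d2 = np.sum((test[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (expanded[nbr] ** 2)[None, :], axis=1)
            n_acc = int(np.sum(~buried))
        else:
            n_acc = n_sphere_points
        out[i] = 4.0 * np.pi * ri * ri * n_acc / n_sphere_points
    return out


def compute_asa(structure: StructureModel, probe_radius: float = 1.4,
                n_sphere_points: int = 960) -> ASAProfile:
    """Per-residue ASA and rASA of a structure (subunit or complex)."""
    per_atom = atom_asa(structure.coords, structure.vdw_radii,
                        probe_radius=probe_radius,
                        n_sphere_points=n_sphere_points)
    n_res = structure.n_residues
    res_asa = np.zeros(n_res, dtype=float)
    np.add.at(res_asa, structure.atom_residue, per_atom)
    rasa = np.array([
        relative_asa(res_asa[i], structure.residues[i].name)
        for i in range(n_res)
    ])
    return ASAProfile(
        residues=list(structure.residues),
        asa=res_asa,
        rasa=rasa,
        atom_asa=per_atom,
        probe_radius=probe_radius,
        n_points=n_sphere_points,
        source_id=structure.source_id,
    )


def relative_asa(asa: float, residue_name: str, strict: bool = False) -> float:
    """ASA divided by the residue-type reference maximum.

    Unknown residue types use the mean reference value unless ``strict``.
    """
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    ref = MAX_ASA_TIEN_2013.get(residue_name.upper())
    if ref is None:
        if strict:
            raise KeyError(f"no reference ASA for residue type {residue_name!r}")
        ref = float(np.mean(list(MAX_ASA_TIEN_2013.values())))
    return asa / ref
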