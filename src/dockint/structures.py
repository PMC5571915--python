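"""Coordinate model for protein subunits and complexes.

A :class:`StructureModel` is a flat, numpy-backed collection of heavy atoms
grouped into residues.  Only standard amino-acid ATOM records are retained:
hydrogens, waters, HETATM records and alternate conformers other than the
first are dropped at parse time, so every downstream distance or surface
computation sees a single, unambiguous set of coordinates.

Parsing is delegated to :mod:`gemmi`; this module only validates the raw
text (gemmi silently zero-fills malformed numeric fields) and flattens the
hierarchy into arrays.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "PDBParseError",
    "ResidueKey",
    "StructureModel",
    "parse_structure",
    "VDW_RADII",
    "THREE_TO_ONE",
]

# Bondi-style van der Waals radii (Angstrom) for the elements that occur in
# standard amino acids; anything else falls back to carbon with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common non-standard residues with an obvious standard parent.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted as atomic coordinates."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue within a structure (author numbering)."""

    chain_id: str
    number: int
    icode: str = ""
    name: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain_id}/{self.name}{self.number}{self.icode}"


@dataclass
class StructureModel:
    """Heavy atoms of one subunit or complex, grouped into residues.

    Attributes
    ----------
    coords : (n_atoms, 3) float array, Angstrom.
    vdw_radii : (n_atoms,) float array.
    elements : (n_atoms,) array of element symbols.
    atom_names : (n_atoms,) array of PDB atom names (CA, CB, ...).
    atom_residue : (n_atoms,) int array, index into ``residues``.
    residues : ordered list of :class:`ResidueKey`, unique.
    source_id : free-text identifier for provenance.
    """

    coords: np.ndarray
    vdw_radii: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    atom_residue: np.ndarray
    residues: list[ResidueKey]
    source_id: str = ""
    _residue_index: dict[ResidueKey, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if np.any(self.vdw_radii <= 0):
            raise ValueError("van der Waals radii must be positive")
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        if self._residue_index is None:
            self._residue_index = {k: i for i, k in enumerate(self.residues)}
        if len(self._residue_index) != len(self.residues):
            raise ValueError("duplicate residue keys")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> set[str]:
        return {k.chain_id for k in self.residues}

    def residue_atoms(self, key: ResidueKey) -> np.ndarray:
        """Coordinates of the atoms of one residue."""
        idx = self._residue_index.get(key)
        if idx is None:
            raise KeyError(f"residue {key} not in structure {self.source_id!r}")
        return self.coords[self.atom_residue == idx]

    def chain_mask(self, chain_ids: set[str]) -> np.ndarray:
        """Boolean per-atom mask selecting the given chains."""
        res_in = np.array([k.chain_id in chain_ids for k in self.residues])
        return res_in[self.atom_residue]

    def subset(self, chain_ids: set[str], source_id: str | None = None) -> "StructureModel":
        """New model restricted to the given chains."""
        mask = self.chain_mask(chain_ids)
        keep_res = [k for k in self.residues if k.chain_id in chain_ids]
        remap = {self._residue_index[k]: i for i, k in enumerate(keep_res)}
        return StructureModel(
            coords=self.coords[mask],
            vdw_radii=self.vdw_radii[mask],
            elements=self.elements[mask],
            atom_names=self.atom_names[mask],
            atom_residue=np.array([remap[i] for i in self.atom_residue[mask]], dtype=int),
            residues=keep_res,
            source_id=source_id or self.source_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "StructureModel":
        """Rigidly transformed copy: rotate about ``center`` then translate."""
        c = np.mean(self.coords, axis=0) if center is None else np.asarray(center, float)
        new = (self.coords - c) @ np.asarray(rotation, float).T + c + np.asarray(translation, float)
        return StructureModel(
            coords=new,
            vdw_radii=self.vdw_radii,
            elements=self.elements,
            atom_names=self.atom_names,
            atom_residue=self.atom_residue,
            residues=self.residues,
            source_id=self.source_id,
        )

    def sequence(self, chain_id: str) -> tuple[str, list[ResidueKey]]:
        """One-letter sequence of a chain plus the residue keys in order."""
        keys = [k for k in self.residues if k.chain_id == chain_id]
        seq = "".join(THREE_TO_ONE.get(k.name, "X") for k in keys)
        return seq, keys

    @staticmethod
    def merge(a: "StructureModel", b: "StructureModel", source_id: str = "") -> "StructureModel":
        """Concatenate two models (chains must not collide in residue keys)."""
        residues = list(a.residues) + list(b.residues)
        return StructureModel(
            coords=np.vstack([a.coords, b.coords]) if a.n_atoms and b.n_atoms
            else (a.coords if b.n_atoms == 0 else b.coords),
            vdw_radii=np.concatenate([a.vdw_radii, b.vdw_radii]),
            elements=np.concatenate([a.elements, b.elements]),
            atom_names=np.concatenate([a.atom_names, b.atom_names]),
            atom_residue=np.concatenate([a.atom_residue, b.atom_residue + a.n_residues]),
            residues=residues,
            source_id=source_id or f"{a.source_id}+{b.source_id}",
        )


def _validate_atom_lines(pdb_text: str) -> None:
    """gemmi tolerates garbage numeric fields; reject them with a line number."""
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_atom += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None
    if n_atom == 0:
        raise PDBParseError("no ATOM records found")


def parse_structure(pdb_text: str, chain_filter: set[str] | None = None,
                    source_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Keeps heavy atoms of standard amino acids from MODEL 1 only.  Alternate
    locations: blank or 'A' retained.  Non-standard residues are mapped to a
    standard parent when one is known (e.g. MSE -> MET), otherwise skipped
    with a warning.

    Parameters
    ----------
    pdb_text : PDB-format text with at least one ATOM record.
    chain_filter : if given, keep only these chain ids.
    source_id : identifier stored on the returned model.
    """
    _validate_atom_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no coordinate model in PDB text")
    model = st[0]

    coords: list[tuple[float, float, float]] = []
    radii: list[float] = []
    elements: list[str] = []
    atom_names: list[str] = []
    atom_residue: list[int] = []
    residues: list[ResidueKey] = []
    warned_elements: set[str] = set()

    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            name = res.name.strip().upper()
            if name in NONSTANDARD_PARENT:
                name = NONSTANDARD_PARENT[name]
            if name not in THREE_TO_ONE:
                if res.het_flag == "H" and name not in ("HOH", "WAT"):
                    warnings.warn(f"skipping non-standard residue {res.name} "
                                  f"{chain.name}{res.seqid.num}", stacklevel=2)
                continue
            atoms = []
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                atoms.append(atom)
            if not atoms:
                continue
            key = ResidueKey(chain.name, res.seqid.num,
                             res.seqid.icode.strip(), name)
            ridx = len(residues)
            residues.append(key)
            for atom in atoms:
                el = atom.element.name.upper()
                r = VDW_RADII.get(el)
                if r is None:
                    if el not in warned_elements:
                        warnings.warn(f"unknown element {el!r}: using "
                                      f"{DEFAULT_VDW_RADIUS} A radius", stacklevel=2)
                        warned_elements.add(el)
                    r = DEFAULT_VDW_RADIUS
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                radii.append(r)
                elements.append(el)
                atom_names.append(atom.name)
                atom_residue.append(ridx)

    if not residues:
        raise PDBParseError("no standard amino-acid ATOM records after filtering")
    return StructureModel(
        coords=np.array(coords, dtype=float),
        vdw_radii=np.array(radii, dtype=float),
        elements=np.array(elements),
        atom_names=np.array(atom_names),
        atom_residue=np.array(atom_residue, dtype=int),
        residues=residues,
        source_id=source_id,
    )


def parse_structure_file(path, chain_filter: set[str] | None = None,
                         source_id: str = "") -> StructureModel:
    """Read a PDB file from disk; see :func:`parse_structure`."""
    with io.open(path, "r") as fh:
        text = fh.read()
    return parse_structure(text, chain_filter=chain_filter,
                           source_id=source_id or str(path))
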