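"""Core / interface / non-interacting-surface classification.

A residue is *core* when its average relative ASA over all available
structures of the protein is below 0.1.  Exposed residues are *interface*
when any of their atoms lies within 10 A of any atom of a partner protein
in any complex; the remaining exposed residues are non-interacting surface.
Each residue receives exactly one label.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .sasa import ASAProfile
from .structures import ResidueKey, StructureModel

__all__ = [
    "LocationLabel",
    "classify_residues",
    "min_interresidue_distance",
    "contacting_residues",
]


class LocationLabel(enum.Enum):
    CORE = "core"
    INTERFACE = "interface"
    NON_INTERFACE_SURFACE = "non_interface_surface"


def min_interresidue_distance(structure: StructureModel, key_a: ResidueKey,
                              key_b: ResidueKey) -> float:
    """Minimum atom-atom Euclidean distance between two residues (A)."""
    xa = structure.residue_atoms(key_a)
    xb = structure.residue_atoms(key_b)
    return float(cdist(xa, xb).min())


def contacting_residues(complex_structure: StructureModel,
                        partner_chains: set[str],
                        cutoff: float = 10.0) -> set[ResidueKey]:
    """Residues outside ``partner_chains`` with any atom within ``cutoff``
    of any partner-chain atom."""
    pmask = complex_structure.chain_mask(partner_chains)
    if not pmask.any() or pmask.all():
        return set()
    partner_xyz = complex_structure.coords[pmask]
    own_xyz = complex_structure.coords[~pmask]
    own_res = complex_structure.atom_residue[~pmask]
    tree = cKDTree(partner_xyz)
    # distance to the nearest partner atom, per own atom
    d, _ = tree.query(own_xyz, k=1)
    hit = d <= cutoff
    keys = set()
    for ridx in np.unique(own_res[hit]):
        keys.add(complex_structure.residues[ridx])
    return keys


def average_rasa(profiles: list[ASAProfile]) -> dict[ResidueKey, float]:
    """Mean rASA per residue over the structures that contain it."""
    sums: dict[ResidueKey, float] = {}
    counts: dict[ResidueKey, int] = {}
    for prof in profiles:
        for key, val in zip(prof.residues, prof.rasa):
            sums[key] = sums.get(key, 0.0) + float(val)
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def classify_residues(
    subunit_profiles: list[ASAProfile],
    partner_structures: list[tuple[StructureModel, set[str]]],
    contact_cutoff: float = 10.0,
    core_cutoff: float = 0.1,
) -> dict[ResidueKey, LocationLabel]:
    """Partition residues into core / interface / non-interacting surface.

    Parameters
    ----------
    subunit_profiles : ASA profiles computed on the *unbound* subunit, one
        per available structure of the protein (rASA values are averaged
        when a residue appears in several).
    partner_structures : (complex model, partner chain ids) pairs; a
        residue in contact with partner atoms in any complex is interface.
    contact_cutoff : interface distance rule, A.
    core_cutoff : rASA below which a residue is core.

    Raises
    ------
    KeyError : a residue present in a complex is missing from every ASA
        profile, so its burial cannot be decided.
    """
    if not subunit_profiles:
        raise ValueError("at least one ASA profile required")
    avg = average_rasa(subunit_profiles)

    in_contact: set[ResidueKey] = set()
    for cplx, partner_chains in partner_structures:
        contacts = contacting_residues(cplx, partner_chains, cutoff=contact_cutoff)
        missing = [k for k in contacts if k not in avg]
        if missing:
            raise KeyError(
                "residues present in complex but absent from ASA profiles: "
                + ", ".join(str(k) for k in sorted(missing))
            )
        in_contact |= contacts

    labels: dict[ResidueKey, LocationLabel] = {}
    for key, rasa in avg.items():
        if rasa < core_cutoff:
            labels[key] = LocationLabel.CORE
        elif key in in_contact:
            labels[key] = LocationLabel.INTERFACE
        else:
            labels[key] = LocationLabel.NON_INTERFACE_SURFACE
    return labels
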