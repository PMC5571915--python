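"""Normalized interface propensity (NIP) from low-energy docking poses.

For every residue the averaged buried surface (ABS) is the relative loss
of solvent-accessible area between the unbound subunit and the mean over
the lowest-energy docking poses:

    ABS_i = (ASA_unbound,i - mean_poses(ASA_i)) / ASA_unbound,i

ABS is normalized per protein to the NIP scale, which is zero at the mean
ABS and one at the maximum:

    NIP_i = (ABS_i - mean(ABS)) / (max(ABS) - mean(ABS))

Residues with NIP >= 0.2 are predicted binding hot-spots, and the final
interface prediction is the *extended patch*: the hot-spots plus every
surface residue (rASA > 0.1) within 10 A of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .docking import DockingRun
from .energy import select_lowest
from .sasa import ASAProfile, compute_asa
from .structures import ResidueKey, StructureModel

__all__ = [
    "NIPProfile",
    "averaged_buried_surface",
    "normalize_nip",
    "predict_hotspots",
    "extend_patch",
    "pose_asa_matrix",
    "nip_from_run",
    "predict_interface_for_protein",
]

NIP_HOTSPOT_CUTOFF = 0.2
PATCH_RADIUS = 10.0
CORE_RASA = 0.1


@dataclass
class NIPProfile:
    """Per-residue ABS/NIP values and the derived interface flags."""

    residues: list[ResidueKey]
    abs_values: np.ndarray
    nip: np.ndarray
    hotspots: set[ResidueKey]
    extended_interface: set[ResidueKey]
    n_poses_used: int
    partner_id: str = ""
    per_partner: dict = field(default_factory=dict)  # partner_id -> (abs, nip)

    def nip_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residues, self.nip))


def averaged_buried_surface(unbound_asa: ASAProfile,
                            pose_asa: np.ndarray) -> np.ndarray:
    """ABS per residue from unbound ASA and per-pose bound ASA.

    ``pose_asa`` has shape (n_poses, n_residues) in the residue order of
    ``unbound_asa``.  Residues with zero unbound ASA get ABS 0.
    """
    pose_asa = np.atleast_2d(np.asarray(pose_asa, dtype=float))
    if pose_asa.shape[0] == 0:
        raise ValueError("at least one pose required")
    if pose_asa.shape[1] != len(unbound_asa.residues):
        raise ValueError(
            f"pose ASA has {pose_asa.shape[1]} residues but the unbound "
            f"profile has {len(unbound_asa.residues)}")
    unbound = unbound_asa.asa
    mean_bound = pose_asa.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_vals = np.where(unbound > 0.0,
                            (unbound - mean_bound) / np.where(unbound > 0, unbound, 1.0),
                            0.0)
    return abs_vals


def normalize_nip(abs_profile: np.ndarray) -> np.ndarray:
    """Affine normalization of ABS: mean maps to 0, maximum to 1.

    A flat profile (max equals mean) yields all-zero NIP.
    """
    abs_profile = np.asarray(abs_profile, dtype=float)
    if abs_profile.size == 0:
        raise ValueError("empty ABS profile")
    mu = abs_profile.mean()
    span = abs_profile.max() - mu
    if span <= 1e-12:
        return np.zeros_like(abs_profile)
    return (abs_profile - mu) / span


def predict_hotspots(nip: np.ndarray, residues: list[ResidueKey],
                     cutoff: float = NIP_HOTSPOT_CUTOFF) -> set[ResidueKey]:
    """Residues with NIP greater than or equal to ``cutoff``."""
    if not -1.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (-1, 1]")
    return {k for k, v in zip(residues, nip) if v >= cutoff}


def extend_patch(hotspots: set[ResidueKey], structure: StructureModel,
                 rasa: ASAProfile, radius: float = PATCH_RADIUS,
                 core_rasa: float = CORE_RASA) -> set[ResidueKey]:
    """Hot-spots plus surface residues (rASA > ``core_rasa``) within
    ``radius`` A (minimum atom-atom distance) of any hot-spot."""
    missing = [k for k in hotspots if k not in structure._residue_index]
    if missing:
        raise KeyError("hot-spots absent from structure: "
                       + ", ".join(str(k) for k in sorted(missing)))
    if not hotspots:
        return set()
    hot_idx = {structure._residue_index[k] for k in hotspots}
    hot_mask = np.isin(structure.atom_residue, list(hot_idx))
    tree = cKDTree(structure.coords[hot_mask])
    d, _ = tree.query(structure.coords, k=1)
    near_res = np.unique(structure.atom_residue[d <= radius])
    rasa_of = rasa.rasa_dict()
    out = set(hotspots)
    for ridx in near_res:
        key = structure.residues[ridx]
        if key in out:
            continue
        if rasa_of.get(key, 0.0) > core_rasa:
            out.add(key)
    return out


def pose_asa_matrix(receptor: StructureModel, ligand: StructureModel,
                    run: DockingRun, side: str = "receptor",
                    probe_radius: float = 1.4,
                    n_sphere_points: int = 960) -> np.ndarray:
    """Per-residue ASA of one subunit in each pose's complex.

    Returns shape (n_poses, n_residues) in the subunit's residue order.
    """
    subunit = receptor if side == "receptor" else ligand
    rows = np.empty((len(run.poses), subunit.n_residues))
    for p, pose in enumerate(run.poses):
        placed = pose.apply(ligand, center=run.ligand_center)
        cplx = StructureModel.merge(receptor, placed, source_id="pose")
        prof = compute_asa(cplx, probe_radius=probe_radius,
                           n_sphere_points=n_sphere_points)
        asa_of = prof.as_dict()
        keys = subunit.residues
        rows[p] = [asa_of[k] for k in keys]
    return rows


def nip_from_run(receptor: StructureModel, ligand: StructureModel,
                 run: DockingRun, side: str = "receptor", k_lowest: int = 100,
                 cutoff: float = NIP_HOTSPOT_CUTOFF,
                 radius: float = PATCH_RADIUS, core_rasa: float = CORE_RASA,
                 probe_radius: float = 1.4,
                 n_sphere_points: int = 960) -> NIPProfile:
    """Full NIP pipeline for one docking run and one subunit side."""
    if not run.rescored:
        raise ValueError("run must be rescored; energies are required "
                         "to pick the lowest-energy poses")
    best = select_lowest(run, k=min(k_lowest, len(run.poses)))
    subunit = receptor if side == "receptor" else ligand
    unbound = compute_asa(subunit, probe_radius=probe_radius,
                          n_sphere_points=n_sphere_points)
    mat = pose_asa_matrix(receptor, ligand, best, side=side,
                          probe_radius=probe_radius,
                          n_sphere_points=n_sphere_points)
    abs_vals = averaged_buried_surface(unbound, mat)
    nip = normalize_nip(abs_vals)
    hot = predict_hotspots(nip, unbound.residues, cutoff=cutoff)
    ext = extend_patch(hot, subunit, unbound, radius=radius,
                       core_rasa=core_rasa)
    partner = ligand.source_id if side == "receptor" else receptor.source_id
    return NIPProfile(
        residues=list(unbound.residues),
        abs_values=abs_vals,
        nip=nip,
        hotspots=hot,
        extended_interface=ext,
        n_poses_used=len(best.poses),
        partner_id=partner,
        per_partner={partner: (abs_vals, nip)},
    )


def predict_interface_for_protein(
        profiles: list[NIPProfile]) -> NIPProfile:
    """Union of per-partner predictions for one protein.

    Hot-spot and extended-interface flags are unioned over partners; ABS
    and NIP are kept per partner (the merged arrays report the per-residue
    maximum, the value that drives the union flags).
    """
    if not profiles:
        raise ValueError("at least one per-partner profile required")
    residues: list[ResidueKey] = []
    seen = set()
    for prof in profiles:
        for k in prof.residues:
            if k not in seen:
                seen.add(k)
                residues.append(k)
    idx = {k: i for i, k in enumerate(residues)}
    abs_max = np.full(len(residues), -np.inf)
    nip_max = np.full(len(residues), -np.inf)
    per_partner: dict = {}
    hot: set[ResidueKey] = set()
    ext: set[ResidueKey] = set()
    n_poses = 0
    for prof in profiles:
        for k, a, v in zip(prof.residues, prof.abs_values, prof.nip):
            i = idx[k]
            abs_max[i] = max(abs_max[i], a)
            nip_max[i] = max(nip_max[i], v)
        per_partner.update(prof.per_partner)
        hot |= prof.hotspots
        ext |= prof.extended_interface
        n_poses = max(n_poses, prof.n_poses_used)
    return NIPProfile(
        residues=residues,
        abs_values=abs_max,
        nip=nip_max,
        hotspots=hot,
        extended_interface=ext,
        n_poses_used=n_poses,
        partner_id="+".join(sorted(per_partner)),
        per_partner=per_partner,
    )
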