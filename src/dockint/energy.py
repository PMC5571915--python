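"""Energy rescoring of docking poses.

Each candidate pose is scored by a weighted sum of three intermolecular
terms, mirroring the composition used by energy-based rescoring protocols
for rigid docking:

* electrostatics — Coulomb with a distance-dependent dielectric
  ``eps(r) = 4r``, truncated per pair to ``+/- elec_cap``;
* van der Waals — 6-12 potential on vdW-radius sums, the repulsive branch
  capped per pair at ``vdw_cap`` so steric clashes cost a bounded amount;
* desolvation — atomic solvation parameters times the surface area buried
  on complexation, estimated with a pairwise spherical-cap approximation.

All constants are configurable through :class:`EnergyParams` and recorded
alongside the run, since they determine the ranking exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .docking import DockingRun, Pose
from .structures import StructureModel

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyParams",
    "EnergyScore",
    "assign_charges",
    "score_pose",
    "rescore",
    "select_lowest",
]

COULOMB_CONSTANT = 332.0  # kcal*A/(mol*e^2)

# Formal side-chain charges at neutral pH, placed evenly on side-chain atoms.
RESIDUE_CHARGE: dict[str, float] = {
    "ARG": +1.0, "LYS": +1.0, "ASP": -1.0, "GLU": -1.0, "HIS": +0.1,
}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Atomic solvation parameters, kcal/(mol*A^2): apolar burial favourable,
# polar burial penalized.
SOLVATION_PARAMS: dict[str, float] = {
    "C": -0.010, "S": -0.012, "N": +0.006, "O": +0.009,
}


@dataclass
class EnergyParams:
    """Weights, caps and cutoffs of the scoring function."""

    w_elec: float = 1.0
    w_desolv: float = 1.0
    w_vdw: float = 0.1
    elec_cap: float | None = 1.0       # per-pair |E| bound; None = uncapped
    vdw_cap: float | None = 1.0        # per-pair repulsion bound
    vdw_epsilon: float = 0.1           # well depth, kcal/mol
    cutoff: float = 12.0               # pair cutoff, A
    receptor_charges: np.ndarray | None = None   # override per-atom charges
    ligand_charges: np.ndarray | None = None


@dataclass
class EnergyScore:
    """Component energies of one pose; ``total`` honours the weights."""

    electrostatics: float
    van_der_waals: float
    desolvation: float
    weights: tuple[float, float, float] = (1.0, 1.0, 0.1)  # (elec, desolv, vdw)

    @property
    def total(self) -> float:
        we, wd, wv = self.weights
        return (we * self.electrostatics + wd * self.desolvation
                + wv * self.van_der_waals)


def assign_charges(structure: StructureModel) -> np.ndarray:
    """Coarse per-atom partial charges from residue type.

    The formal side-chain charge of charged residue types is divided evenly
    over the residue's side-chain atoms; backbone atoms and neutral
    residues get zero.
    """
    q = np.zeros(structure.n_atoms)
    for ridx, key in enumerate(structure.residues):
        total = RESIDUE_CHARGE.get(key.name, 0.0)
        if total == 0.0:
            continue
        in_res = structure.atom_residue == ridx
        side = in_res & ~np.isin(structure.atom_names, list(BACKBONE_ATOMS))
        target = side if side.any() else in_res
        q[target] = total / target.sum()
    return q


def _pair_terms(rec: StructureModel, lig_coords: np.ndarray,
                q_rec: np.ndarray, q_lig: np.ndarray,
                lig_radii: np.ndarray, lig_elements: np.ndarray,
                params: EnergyParams) -> tuple[float, float, float]:
    d = cdist(rec.coords, lig_coords)
    within = d <= params.cutoff
    if not within.any():
        return 0.0, 0.0, 0.0
    ii, jj = np.nonzero(within)
    r = np.maximum(d[ii, jj], 1e-3)

    # Coulomb with eps(r) = 4r  ->  q_i q_j * k / (4 r^2)
    e_pair = COULOMB_CONSTANT * q_rec[ii] * q_lig[jj] / (4.0 * r * r)
    if params.elec_cap is not None:
        e_pair = np.clip(e_pair, -params.elec_cap, params.elec_cap)
    elec = float(e_pair.sum())

    # 6-12 van der Waals on radius sums, repulsion capped
    s = rec.vdw_radii[ii] + lig_radii[jj]
    sr6 = (s / r) ** 6
    v_pair = params.vdw_epsilon * (sr6 * sr6 - 2.0 * sr6)
    if params.vdw_cap is not None:
        v_pair = np.minimum(v_pair, params.vdw_cap)
    vdw = float(v_pair.sum())

    # pairwise spherical-cap burial on probe-expanded spheres
    probe = 1.4
    ra = rec.vdw_radii[ii] + probe
    rb = lig_radii[jj] + probe
    overlap = d[ii, jj] < (ra + rb)
    desolv = 0.0
    if overlap.any():
        io_, jo = ii[overlap], jj[overlap]
        ro = np.maximum(d[io_, jo], 1e-3)
        rao, rbo = ra[overlap], rb[overlap]
        # cap height on each sphere of the intersecting pair
        ha = np.clip(rao - (ro * ro + rao * rao - rbo * rbo) / (2.0 * ro),
                     0.0, 2.0 * rao)
        hb = np.clip(rbo - (ro * ro + rbo * rbo - rao * rao) / (2.0 * ro),
                     0.0, 2.0 * rbo)
        area_a = 2.0 * np.pi * rao * ha
        area_b = 2.0 * np.pi * rbo * hb
        # accumulate per atom, clamp at the atom's full expanded sphere
        buried_rec = np.zeros(rec.n_atoms)
        np.add.at(buried_rec, io_, area_a)
        buried_rec = np.minimum(
            buried_rec, 4.0 * np.pi * (rec.vdw_radii + probe) ** 2)
        buried_lig = np.zeros(len(lig_coords))
        np.add.at(buried_lig, jo, area_b)
        buried_lig = np.minimum(
            buried_lig, 4.0 * np.pi * (lig_radii + probe) ** 2)
        asp_rec = np.array([SOLVATION_PARAMS.get(e, -0.010) for e in rec.elements])
        asp_lig = np.array([SOLVATION_PARAMS.get(e, -0.010) for e in lig_elements])
        desolv = float((asp_rec * buried_rec).sum() + (asp_lig * buried_lig).sum())
    return elec, vdw, desolv


def score_pose(receptor: StructureModel, ligand: StructureModel, pose: Pose,
               params: EnergyParams | None = None,
               ligand_center: np.ndarray | None = None) -> EnergyScore:
    """Score one pose; the ligand is transformed about ``ligand_center``."""
    params = params or EnergyParams()
    center = (ligand.coords.mean(axis=0) if ligand_center is None
              else np.asarray(ligand_center, float))
    q_rec = (params.receptor_charges if params.receptor_charges is not None
             else assign_charges(receptor))
    q_lig = (params.ligand_charges if params.ligand_charges is not None
             else assign_charges(ligand))
    placed = pose.apply(ligand, center=center)
    elec, vdw, desolv = _pair_terms(receptor, placed.coords, q_rec, q_lig,
                                    ligand.vdw_radii, ligand.elements, params)
    return EnergyScore(electrostatics=elec, van_der_waals=vdw,
                       desolvation=desolv,
                       weights=(params.w_elec, params.w_desolv, params.w_vdw))


def rescore(receptor: StructureModel, ligand: StructureModel,
            run: DockingRun, params: EnergyParams | None = None) -> DockingRun:
    """Attach an :class:`EnergyScore` to every pose of a run."""
    params = params or EnergyParams()
    q_rec = (params.receptor_charges if params.receptor_charges is not None
             else assign_charges(receptor))
    q_lig = (params.ligand_charges if params.ligand_charges is not None
             else assign_charges(ligand))
    pinned = replace(params, receptor_charges=q_rec, ligand_charges=q_lig)
    energies = [
        score_pose(receptor, ligand, pose, pinned,
                   ligand_center=run.ligand_center)
        for pose in run.poses
    ]
    out = DockingRun(**{**run.__dict__})
    out.energies = energies
    out.config = {**run.config,
                  "weights": (params.w_elec, params.w_desolv, params.w_vdw),
                  "elec_cap": params.elec_cap, "vdw_cap": params.vdw_cap,
                  "vdw_epsilon": params.vdw_epsilon, "cutoff": params.cutoff}
    return out


def select_lowest(run: DockingRun, k: int = 100) -> DockingRun:
    """Keep the ``k`` lowest-total-energy poses of a rescored run.

    Ties are broken by shape score (descending) and then pose index, so the
    selection is deterministic.
    """
    if not run.rescored:
        raise ValueError("run must be rescored before selection")
    if k > len(run.poses):
        warnings.warn(f"requested {k} poses but run holds {len(run.poses)}",
                      stacklevel=2)
    order = sorted(
        range(len(run.poses)),
        key=lambda i: (run.energies[i].total, -run.poses[i].shape_score, i),
    )[:k]
    out = DockingRun(**{**run.__dict__})
    out.poses = [run.poses[i] for i in order]
    out.energies = [run.energies[i] for i in order]
    return out
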