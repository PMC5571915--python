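"""Rigid-body docking by grid shape correlation.

Receptor and ligand are discretized on cubic grids in the
Katchalski-Katzir fashion: cells in a thin contact shell just outside the
receptor's van der Waals surface are worth +1, cells inside the surface
carry a large negative penalty, and every cell inside the ligand surface
is worth +1.  The shape score of a relative translation is the sum of
products of overlapping cells — positive for surface complementarity,
strongly negative for interpenetration — evaluated for all translations
at once by FFT cross-correlation.  For each sampled ligand rotation the best-scoring
translations are kept, and the global list is truncated to ``n_keep``
candidate poses, which are then rescored by the energy model in
:mod:`dockint.energy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import StructureModel

__all__ = [
    "Grid",
    "Pose",
    "DockingRun",
    "discretize",
    "correlate_fft",
    "correlate_direct",
    "rotation_set",
    "generate_poses",
]

INTERIOR_PENALTY = -15.0
MAX_GRID_CELLS = 40_000_000


@dataclass
class Grid:
    """Cubic grid of cell values with a physical origin."""

    values: np.ndarray   # 3-D float array
    origin: np.ndarray   # physical position of cell (0,0,0) centre, A
    spacing: float       # A

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Pose:
    """Rigid placement of the ligand relative to the receptor.

    ``transform`` rotates ligand coordinates about the ligand centroid and
    then translates; determinant of ``rotation`` is +1.
    """

    rotation: np.ndarray       # 3x3 orthonormal
    translation: np.ndarray    # 3-vector, A
    shape_score: float
    rank: int = -1
    rotation_index: int = -1

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        # tolerance admits matrices round-tripped through 6-decimal text
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-4:
            raise ValueError("rotation determinant must be +1")

    def apply(self, ligand: StructureModel, center: np.ndarray) -> StructureModel:
        return ligand.transformed(self.rotation, self.translation, center=center)


@dataclass
class DockingRun:
    """One docking calculation: parameters plus scored candidate poses."""

    receptor_id: str
    ligand_id: str
    spacing: float
    n_rotations: int
    n_keep: int
    seed: int
    ligand_center: np.ndarray
    poses: list[Pose]
    energies: list = field(default_factory=list)   # EnergyScore, parallel to poses
    config: dict = field(default_factory=dict)

    @property
    def rescored(self) -> bool:
        return len(self.energies) == len(self.poses) and len(self.poses) > 0


def _signed_distance(structure: StructureModel, origin: np.ndarray,
                     shape: tuple, spacing: float, reach: float) -> np.ndarray:
    """Per-cell min over atoms of (distance to atom centre - vdW radius).

    Only evaluated within ``reach`` of each atom surface; farther cells
    stay at +inf.  The cell nearest each atom centre is always marked
    interior, so every atom registers even on coarse grids.
    """
    sdist = np.full(shape, np.inf)
    for xyz, r in zip(structure.coords, structure.vdw_radii):
        lo = np.floor((xyz - r - reach - origin) / spacing).astype(int)
        hi = np.ceil((xyz + r + reach - origin) / spacing).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(shape) - 1)
        if np.any(hi < lo):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        centers = origin + spacing * np.stack(
            np.meshgrid(*ax, indexing="ij"), axis=-1)
        d = np.sqrt(np.sum((centers - xyz) ** 2, axis=-1)) - r
        box = sdist[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        np.minimum(box, d, out=box)
        nearest = np.clip(np.round((xyz - origin) / spacing).astype(int),
                          0, np.array(shape) - 1)
        sdist[tuple(nearest)] = min(sdist[tuple(nearest)], -1e-9)
    return sdist


def discretize(structure: StructureModel, spacing: float,
               surface_thickness: float = 1.5, role: str = "receptor",
               interior_penalty: float = INTERIOR_PENALTY,
               padding: float = 2.0) -> Grid:
    """Discretize a structure onto a cubic grid.

    ``role='receptor'``: cells inside the van der Waals surface get the
    (negative) ``interior_penalty``; cells in a shell of width
    ``surface_thickness`` just outside the surface get value 1.
    ``role='ligand'``: cells inside the surface get value 1.  Scoring a
    translation therefore rewards ligand atoms sitting in the receptor's
    contact shell and heavily punishes interpenetration.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if structure.n_atoms == 0:
        raise ValueError("cannot discretize an empty structure")
    rmax = structure.vdw_radii.max()
    pad = rmax + surface_thickness + padding
    lo = structure.coords.min(axis=0) - pad
    hi = structure.coords.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    if int(np.prod(shape)) > MAX_GRID_CELLS:
        raise ValueError(
            f"grid of {shape} exceeds the cell budget; use a larger spacing")
    sdist = _signed_distance(structure, lo, shape, spacing,
                             reach=surface_thickness + spacing)
    values = np.zeros(shape, dtype=float)
    if role == "ligand":
        values[sdist < 0] = 1.0
    elif role == "receptor":
        values[(sdist >= 0) & (sdist <= surface_thickness)] = 1.0
        values[sdist < 0] = interior_penalty
    else:
        raise ValueError(f"unknown role {role!r}")
    return Grid(values=values, origin=lo.copy(), spacing=spacing)


def correlate_fft(receptor: np.ndarray, ligand: np.ndarray) -> np.ndarray:
    """Full linear cross-correlation ``c[s] = sum_x R[x] L[x - s]`` by FFT.

    Output shape is ``R.shape + L.shape - 1``; shift ``s`` along each axis
    runs from ``-(L_dim - 1)`` to ``R_dim - 1`` and is stored at index
    ``s + L_dim - 1``.
    """
    out_shape = tuple(r + l - 1 for r, l in zip(receptor.shape, ligand.shape))
    axes = (0, 1, 2)
    fr = np.fft.rfftn(receptor, out_shape, axes=axes)
    fl = np.fft.rfftn(ligand, out_shape, axes=axes)
    corr = np.fft.irfftn(fr * np.conj(fl), out_shape, axes=axes)
    # conj in frequency space corresponds to coordinate reversal: reorder
    # so that index s + (L-1) holds shift s
    corr = np.roll(corr, tuple(l - 1 for l in ligand.shape), axis=(0, 1, 2))
    return corr


def correlate_direct(receptor: np.ndarray, ligand: np.ndarray) -> np.ndarray:
    """Brute-force counterpart of :func:`correlate_fft` (small grids only)."""
    rs = receptor.shape
    ls = ligand.shape
    out = np.zeros(tuple(r + l - 1 for r, l in zip(rs, ls)))
    nz = np.argwhere(ligand != 0)
    for idx in nz:
        val = ligand[tuple(idx)]
        sx, sy, sz = (np.arange(rs[d]) - idx[d] + ls[d] - 1 for d in range(3))
        out[np.ix_(sx, sy, sz)] += receptor * val
    return out


def rotation_set(n: int, seed: int) -> np.ndarray:
    """Deterministic quasi-uniform rotation matrices, shape (n, 3, 3).

    The identity is always the first element so that a fixture posed in its
    docked orientation is reachable at any sample size.
    """
    if n < 1:
        raise ValueError("need at least one rotation")
    mats = [np.eye(3)]
    if n > 1:
        rng = np.random.default_rng(seed)
        mats.extend(Rotation.random(n - 1, random_state=rng).as_matrix())
    return np.array(mats)


def generate_poses(receptor: StructureModel, ligand: StructureModel,
                   n_rotations: int, spacing: float, n_keep: int = 10000,
                   seed: int = 0, top_per_rotation: int = 100,
                   surface_thickness: float = 1.5) -> DockingRun:
    """Sample rigid-body poses by FFT shape correlation.

    For each rotation the ``top_per_rotation`` best translations are
    extracted from the correlation map; the global candidate list is then
    truncated to the ``n_keep`` best shape scores (ties broken by rotation
    then cell order).  Only poses with positive shape score are candidates.
    """
    if receptor.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("receptor and ligand must be non-empty")
    rgrid = discretize(receptor, spacing, surface_thickness, role="receptor")
    rots = rotation_set(n_rotations, seed)
    lig_center = ligand.coords.mean(axis=0)

    candidates: list[tuple[float, int, int, np.ndarray]] = []
    for ri, rot in enumerate(rots):
        rotated = ligand.transformed(rot, np.zeros(3), center=lig_center)
        lgrid = discretize(rotated, spacing, surface_thickness, role="ligand")
        corr = correlate_fft(rgrid.values, lgrid.values)
        flat = corr.ravel()
        k = min(top_per_rotation, flat.size)
        # stable top-k: partial select then deterministic ordering
        part = np.argpartition(-flat, k - 1)[:k]
        part = part[np.lexsort((part, -flat[part]))]
        lshape = np.array(lgrid.shape)
        for cell in part:
            score = float(flat[cell])
            if score <= 0:
                break
            sidx = np.array(np.unravel_index(cell, corr.shape))
            shift = sidx - (lshape - 1)
            trans = (rgrid.origin - lgrid.origin) + shift * spacing
            candidates.append((score, ri, int(cell), (rot, trans)))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    if n_keep > len(candidates):
        warnings.warn(
            f"requested {n_keep} poses but only {len(candidates)} candidates",
            stacklevel=2)
    kept = candidates[:n_keep]
    poses = [
        Pose(rotation=rot, translation=trans, shape_score=score,
             rank=i, rotation_index=ri)
        for i, (score, ri, _cell, (rot, trans)) in enumerate(kept)
    ]
    return DockingRun(
        receptor_id=receptor.source_id,
        ligand_id=ligand.source_id,
        spacing=spacing,
        n_rotations=n_rotations,
        n_keep=n_keep,
        seed=seed,
        ligand_center=lig_center,
        poses=poses,
        config={
            "top_per_rotation": top_per_rotation,
            "surface_thickness": surface_thickness,
            "interior_penalty": INTERIOR_PENALTY,
        },
    )
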