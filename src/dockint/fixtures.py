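"""Synthetic inputs: toy complexes, planted variant tables, packaged census.

``make_toy_complex`` builds two rigid pseudo-atom bodies (one backbone and
one side-chain sphere per residue) shaped as square towers that meet
cap-to-cap at a designed pose.  The cap residues of the two bodies carry
complementary formal charges (ARG facing GLU), so energy rescoring favours
near-native poses and the designed interface is recoverable from docking.
The layer spacing is chosen so that, at the designed pose, exactly the cap
residues satisfy the 10 A interface rule — the generator verifies this by
running the classifier on the assembled complex.

``make_variant_fixture`` plants missense variants on labelled residues
with a chosen interface-versus-surface odds ratio for the disease class,
emitting humsavar-dialect text.

``table2_census`` returns the packaged residue/variant counts of the
published six-disease interaction-network census (structural, docking and
combined contexts) for statistics reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .classify import LocationLabel, classify_residues
from .docking import Pose
from .sasa import compute_asa
from .structures import THREE_TO_ONE, ResidueKey, StructureModel
from .variants import ONE_TO_THREE, RegionCensus, VariantCategory

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "VariantFixtureSpec",
    "make_toy_complex",
    "make_variant_fixture",
    "table2_census",
    "write_pdb",
]

LATTICE_SPACING = 5.0       # A between residue columns within a layer
LAYER_SPACING = 7.0         # A between tower layers
CONTACT_GAP = 4.0           # A between the two caps at the designed pose
SIDECHAIN_OFFSET = 1.6      # A, CB offset from CA along +x


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a synthetic two-body complex."""

    n_residues: int = 30          # per body
    interface_size: int = 6       # designed interface residues per body
    seed: int = 0
    unbound_displacement: float = 40.0   # A, how far the ligand starts away

    def __post_init__(self) -> None:
        if not 0 < self.interface_size < self.n_residues:
            raise ValueError("interface size must be positive and smaller "
                             "than the residue count per body")


@dataclass
class ToyComplex:
    receptor: StructureModel
    ligand: StructureModel                 # unbound placement
    ligand_docked: StructureModel
    truth_receptor: set[ResidueKey]
    truth_ligand: set[ResidueKey]
    designed_pose: Pose
    receptor_pdb: str
    ligand_pdb: str


@dataclass(frozen=True)
class VariantFixtureSpec:
    """Parameters of a planted variant table."""

    n_disease: int = 200
    n_polymorphism: int = 100
    n_unclassified: int = 50
    target_or: float = 2.0        # disease odds, interface vs non-interface
    seed: int = 0
    accession: str = "P99999"
    gene: str = "TOY1"

    def __post_init__(self) -> None:
        if self.target_or <= 0:
            raise ValueError("target odds ratio must be positive")


def _cross_section(k: int) -> tuple[int, int]:
    a = max(1, int(np.sqrt(k)))
    while k % a:
        a -= 1
    return a, k // a


LAYER_SPREAD = 0.5          # lateral widening per layer away from the cap


def _tower(n_residues: int, k: int, chain_id: str, z0: float, z_step: float,
           cap_name: str, body_name: str = "ALA") -> StructureModel:
    """Frustum of pseudo-residues: the cap layer (the designed interface)
    sits at z0 and deeper layers spread laterally while receding along
    ``z_step``, so two bodies can only make facial contact cap-to-cap."""
    a, b = _cross_section(k)
    coords, radii, elements, names, atom_res = [], [], [], [], []
    residues: list[ResidueKey] = []
    num = 0
    layer = 0
    while num < n_residues:
        z = z0 + layer * z_step
        spread = 1.0 + LAYER_SPREAD * layer
        for i in range(a):
            for j in range(b):
                if num >= n_residues:
                    break
                num += 1
                name = cap_name if layer == 0 else body_name
                key = ResidueKey(chain_id, num, "", name)
                ridx = len(residues)
                residues.append(key)
                x = (i - (a - 1) / 2.0) * LATTICE_SPACING * spread
                y = (j - (b - 1) / 2.0) * LATTICE_SPACING * spread
                for aname, offset in (("CA", 0.0), ("CB", SIDECHAIN_OFFSET)):
                    coords.append((x + offset, y, z))
                    radii.append(1.70)
                    elements.append("C")
                    names.append(aname)
                    atom_res.append(ridx)
        layer += 1
    return StructureModel(
        coords=np.array(coords), vdw_radii=np.array(radii),
        elements=np.array(elements), atom_names=np.array(names),
        atom_residue=np.array(atom_res), residues=residues,
        source_id=f"toy-{chain_id}",
    )


def write_pdb(structure: StructureModel) -> str:
    """Render a StructureModel as minimal PDB-format text."""
    lines = []
    serial = 0
    for i in range(structure.n_atoms):
        serial += 1
        key = structure.residues[structure.atom_residue[i]]
        name = structure.atom_names[i]
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s} {key.name:>3s} {key.chain_id}"
            f"{key.number:4d}{key.icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{structure.elements[i]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build a complementary two-body fixture with a known interface.

    Deterministic for a given spec (the seed fixes the unbound ligand
    placement).  Raises if the designed pose clashes or if the classifier
    does not reproduce the designed interface exactly.
    """
    k = spec.interface_size
    receptor = _tower(spec.n_residues, k, "A", z0=0.0, z_step=-LAYER_SPACING,
                      cap_name="ARG")
    ligand_docked = _tower(spec.n_residues, k, "B", z0=CONTACT_GAP,
                           z_step=+LAYER_SPACING, cap_name="GLU")

    # clash check at the designed pose
    from scipy.spatial.distance import cdist
    dmin = cdist(receptor.coords, ligand_docked.coords).min()
    if dmin < 3.4:
        raise RuntimeError(f"designed pose clashes (min distance {dmin:.2f} A)")

    truth_receptor = {key for key in receptor.residues if key.name == "ARG"}
    truth_ligand = {key for key in ligand_docked.residues if key.name == "GLU"}

    # self-consistency: the 10 A rule on the assembled complex must recover
    # exactly the designed caps
    cplx = StructureModel.merge(receptor, ligand_docked, source_id="toy-complex")
    labels = classify_residues(
        [compute_asa(receptor), compute_asa(ligand_docked)],
        [(cplx, {"B"}), (cplx, {"A"})],
    )
    got_r = {key for key, lab in labels.items()
             if lab is LocationLabel.INTERFACE and key.chain_id == "A"}
    got_l = {key for key, lab in labels.items()
             if lab is LocationLabel.INTERFACE and key.chain_id == "B"}
    if got_r != truth_receptor or got_l != truth_ligand:
        raise RuntimeError("designed interface does not match the 10 A rule")

    # unbound ligand: seeded random rigid displacement of the docked body
    rng = np.random.default_rng(spec.seed)
    q = Rotation.random(random_state=rng).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = spec.unbound_displacement * direction
    docked_center = ligand_docked.coords.mean(axis=0)
    ligand = ligand_docked.transformed(q, shift, center=docked_center)

    # pose mapping the unbound ligand back onto the docked placement:
    # rotate by q^T about the unbound centroid, translate by -shift
    pose = Pose(rotation=q.T, translation=-shift, shape_score=0.0)
    back = pose.apply(ligand, center=ligand.coords.mean(axis=0))
    assert np.allclose(back.coords, ligand_docked.coords, atol=1e-8)

    return ToyComplex(
        receptor=receptor, ligand=ligand, ligand_docked=ligand_docked,
        truth_receptor=truth_receptor, truth_ligand=truth_ligand,
        designed_pose=pose,
        receptor_pdb=write_pdb(receptor), ligand_pdb=write_pdb(ligand),
    )


def _solve_rates(N_i: int, N_j: int, n: int, target_or: float
                 ) -> tuple[float, float]:
    """Per-residue variant rates (interface, non-interface) whose odds
    ratio equals ``target_or`` and whose expected total count is ``n``."""
    if n > N_i + N_j:
        raise ValueError("more variants requested than labelled residues")

    def rate_i(q: float) -> float:
        o = target_or * q / (1.0 - q)
        return o / (1.0 + o)

    def excess(q: float) -> float:
        return N_i * rate_i(q) + N_j * q - n

    eps = 1e-12
    q = brentq(excess, eps, 1.0 - eps)
    return rate_i(q), q


def make_variant_fixture(spec: VariantFixtureSpec,
                         residue_labels: dict[ResidueKey, LocationLabel]
                         ) -> tuple[str, dict]:
    """Plant variants on labelled residues and emit humsavar-dialect text.

    Disease variants fall on interface vs non-interacting-surface residues
    as independent per-residue Bernoulli draws whose rates realize the
    target odds ratio in expectation; polymorphisms and unclassified
    variants are uniform over all residues.  Sequence position = rank of
    the residue in canonical order.

    Returns the table text and a ground-truth dict with the planted
    per-region counts and the residue-number mapping.
    """
    ordered = sorted(residue_labels)
    pos_of = {key: i + 1 for i, key in enumerate(ordered)}
    interface = [k for k in ordered
                 if residue_labels[k] is LocationLabel.INTERFACE]
    non_interface = [k for k in ordered
                     if residue_labels[k] is LocationLabel.NON_INTERFACE_SURFACE]
    if spec.n_disease and (not interface or not non_interface):
        raise ValueError("need interface and non-interface residues to "
                         "plant disease variants")

    rng = np.random.default_rng(spec.seed)
    placements: list[tuple[ResidueKey, VariantCategory, str]] = []
    n_int = n_non = 0
    if spec.n_disease:
        r_i, r_j = _solve_rates(len(interface), len(non_interface),
                                spec.n_disease, spec.target_or)
        for key in interface:
            if rng.random() < r_i:
                placements.append((key, VariantCategory.DISEASE, "interface"))
                n_int += 1
        for key in non_interface:
            if rng.random() < r_j:
                placements.append((key, VariantCategory.DISEASE,
                                   "non_interface"))
                n_non += 1
    for n_req, cat in ((spec.n_polymorphism, VariantCategory.POLYMORPHISM),
                       (spec.n_unclassified, VariantCategory.UNCLASSIFIED)):
        if n_req == 0:
            continue
        picks = rng.choice(len(ordered), size=min(n_req, len(ordered)),
                           replace=False)
        for i in sorted(picks):
            key = ordered[i]
            region = {LocationLabel.CORE: "core",
                      LocationLabel.INTERFACE: "interface",
                      LocationLabel.NON_INTERFACE_SURFACE: "non_interface"}[
                          residue_labels[key]]
            placements.append((key, cat, region))

    aa_letters = sorted(THREE_TO_ONE.values())
    lines = []
    var_serial = 0
    token = {VariantCategory.DISEASE: "Disease",
             VariantCategory.POLYMORPHISM: "Polymorphism",
             VariantCategory.UNCLASSIFIED: "Unclassified"}
    for key, cat, _region in placements:
        var_serial += 1
        wt = THREE_TO_ONE.get(key.name, "A")
        mut = aa_letters[rng.integers(len(aa_letters))]
        while mut == wt:
            mut = aa_letters[rng.integers(len(aa_letters))]
        change = f"p.{ONE_TO_THREE[wt]}{pos_of[key]}{ONE_TO_THREE[mut]}"
        pheno = ("Synthetic disorder [MIM:000000]"
                 if cat is VariantCategory.DISEASE else "-")
        lines.append(f"{spec.gene:<10}{spec.accession:<12}"
                     f"VAR_{var_serial:06d}  {change:<14}"
                     f"{token[cat]:<14}-            {pheno}")
    text = "\n".join(lines) + ("\n" if lines else "")
    truth = {
        "position_of": pos_of,
        "placements": placements,
        "disease_interface": n_int,
        "disease_non_interface": n_non,
        "n_interface_residues": len(interface),
        "n_non_interface_residues": len(non_interface),
    }
    return text, truth


# Packaged six-disease interaction-network census: residue and nsSNP counts
# by structural location for the structural, docking-model and combined
# contexts.
_CENSUS = {
    "structural": {
        "proteins": (353, 258),
        "residues": {"total": 76168, "core": 21710, "interface": 23779,
                     "non_interface": 30679, "hotspot": 5918,
                     "hotspot_at_interface": 3673},
        "snps": {
            VariantCategory.DISEASE: {"core": 399, "interface": 183,
                                      "non_interface": 250,
                                      "interface_hotspot": 33},
            VariantCategory.POLYMORPHISM: {"core": 118, "interface": 193,
                                           "non_interface": 188,
                                           "interface_hotspot": 46},
            VariantCategory.UNCLASSIFIED: {"core": 102, "interface": 73,
                                           "non_interface": 118,
                                           "interface_hotspot": 17},
        },
    },
    "docking": {
        "proteins": (583, 411),
        "residues": {"total": 189629, "core": 53849, "interface": 55031,
                     "non_interface": 80749, "hotspot": 11839,
                     "hotspot_at_interface": 11839},
        "snps": {
            VariantCategory.DISEASE: {"core": 609, "interface": 370,
                                      "non_interface": 384,
                                      "interface_hotspot": 74},
            VariantCategory.POLYMORPHISM: {"core": 231, "interface": 221,
                                           "non_interface": 399,
                                           "interface_hotspot": 35},
            VariantCategory.UNCLASSIFIED: {"core": 130, "interface": 145,
                                           "non_interface": 126,
                                           "interface_hotspot": 47},
        },
    },
    "combined": {
        "proteins": (603, 424),
        "residues": {"total": 199846, "core": 54936, "interface": 68768,
                     "non_interface": 76142, "hotspot": 16449,
                     "hotspot_at_interface": 14459},
        "snps": {
            VariantCategory.DISEASE: {"core": 629, "interface": 466,
                                      "non_interface": 343,
                                      "interface_hotspot": 109},
            VariantCategory.POLYMORPHISM: {"core": 228, "interface": 331,
                                           "non_interface": 340,
                                           "interface_hotspot": 76},
            VariantCategory.UNCLASSIFIED: {"core": 146, "interface": 178,
                                           "non_interface": 125,
                                           "interface_hotspot": 61},
        },
    },
}


def table2_census(context: str) -> RegionCensus:
    """Packaged six-disease census for one context.

    ``context`` is ``structural`` (complex structures only), ``docking``
    (docking-based models only) or ``combined``.
    """
    try:
        data = _CENSUS[context]
    except KeyError:
        raise KeyError(f"unknown census context {context!r}; expected one of "
                       f"{sorted(_CENSUS)}") from None
    n_prot, n_with = data["proteins"]
    return RegionCensus(
        context=context,
        residue_counts=dict(data["residues"]),
        snp_counts={cat: dict(c) for cat, c in data["snps"].items()},
        n_proteins=n_prot,
        n_proteins_with_snp=n_with,
    )
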