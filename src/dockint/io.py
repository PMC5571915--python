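"""Tab-separated output tables.

All floats are written with fixed precision so that runs with identical
seeds and parameters produce byte-identical files.
"""

from __future__ import annotations

from .classify import LocationLabel
from .docking import DockingRun
from .nip import NIPProfile
from .sasa import ASAProfile
from .structures import ResidueKey
from .variants import RegionCensus, VariantAnnotation, VariantCategory

__all__ = [
    "classification_table",
    "poses_table",
    "nip_table",
    "annotations_table",
    "census_table",
]

_F = "{:.6f}".format


def classification_table(labels: dict[ResidueKey, LocationLabel],
                         profile: ASAProfile, source_id: str = "") -> str:
    header = "source_id\tchain\tresidue_number\tresidue_name\tasa\trasa\tlabel"
    asa = profile.as_dict()
    rasa = profile.rasa_dict()
    lines = [header]
    for key in sorted(labels):
        lines.append("\t".join([
            source_id or profile.source_id,
            key.chain_id, f"{key.number}{key.icode}", key.name,
            _F(asa.get(key, float("nan"))), _F(rasa.get(key, float("nan"))),
            labels[key].value,
        ]))
    return "\n".join(lines) + "\n"


def poses_table(run: DockingRun) -> str:
    header = ("rank\trotation_index\t"
              "r00\tr01\tr02\tr10\tr11\tr12\tr20\tr21\tr22\t"
              "tx\tty\ttz\tshape_score\telec\tvdw\tdesolv\ttotal")
    lines = [header]
    for i, pose in enumerate(run.poses):
        rot = pose.rotation.ravel()
        row = [str(pose.rank), str(pose.rotation_index)]
        row += [_F(v) for v in rot]
        row += [_F(v) for v in pose.translation]
        row.append(_F(pose.shape_score))
        if run.rescored:
            e = run.energies[i]
            row += [_F(e.electrostatics), _F(e.van_der_waals),
                    _F(e.desolvation), _F(e.total)]
        else:
            row += ["", "", "", ""]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def nip_table(profile: NIPProfile) -> str:
    header = "chain\tresidue_number\tresidue_name\tabs\tnip\thotspot\textended_interface"
    lines = [header]
    for key, a, v in zip(profile.residues, profile.abs_values, profile.nip):
        lines.append("\t".join([
            key.chain_id, f"{key.number}{key.icode}", key.name,
            _F(a), _F(v),
            "1" if key in profile.hotspots else "0",
            "1" if key in profile.extended_interface else "0",
        ]))
    return "\n".join(lines) + "\n"


def annotations_table(annotations: list[VariantAnnotation]) -> str:
    header = ("accession\tposition\twt\tmut\tcategory\tlocation\t"
              "hotspot\tevidence\tphenotype")
    lines = [header]
    for ann in annotations:
        rec = ann.record
        lines.append("\t".join([
            rec.protein_accession, str(rec.position), rec.wt_aa, rec.mut_aa,
            rec.category.value,
            ann.location.value if ann.location is not None else "unmapped",
            "1" if ann.hotspot else "0",
            ann.evidence.value, rec.phenotype_text,
        ]))
    return "\n".join(lines) + "\n"


def census_table(census: RegionCensus) -> str:
    lines = ["context\tkind\tcategory\tregion\tcount"]
    for region, count in census.residue_counts.items():
        lines.append(f"{census.context}\tresidues\t-\t{region}\t{count}")
    for cat in VariantCategory:
        for region, count in census.snp_counts[cat].items():
            lines.append(
                f"{census.context}\tsnps\t{cat.value}\t{region}\t{count}")
        if census.unmapped:
            lines.append(f"{census.context}\tsnps\t{cat.value}\tunmapped\t"
                         f"{census.unmapped.get(cat, 0)}")
    return "\n".join(lines) + "\n"


def _parse_resnum(text: str) -> tuple[int, str]:
    digits = ""
    for ch in text:
        if ch.isdigit() or (ch == "-" and not digits):
            digits += ch
        else:
            break
    return int(digits), text[len(digits):]


def read_classification(text: str) -> tuple[dict, dict]:
    """Inverse of :func:`classification_table`: (labels, rasa) dicts."""
    labels: dict[ResidueKey, LocationLabel] = {}
    rasa: dict[ResidueKey, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        _sid, chain, num, name, _asa, ras, label = line.split("\t")
        n, icode = _parse_resnum(num)
        key = ResidueKey(chain, n, icode, name)
        labels[key] = LocationLabel(label)
        rasa[key] = float(ras)
    return labels, rasa


def read_nip(text: str) -> NIPProfile:
    """Inverse of :func:`nip_table`."""
    import numpy as np

    residues, abs_vals, nips = [], [], []
    hot, ext = set(), set()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        chain, num, name, a, v, h, e = line.split("\t")
        n, icode = _parse_resnum(num)
        key = ResidueKey(chain, n, icode, name)
        residues.append(key)
        abs_vals.append(float(a))
        nips.append(float(v))
        if h == "1":
            hot.add(key)
        if e == "1":
            ext.add(key)
    return NIPProfile(residues=residues, abs_values=np.array(abs_vals),
                      nip=np.array(nips), hotspots=hot,
                      extended_interface=ext, n_poses_used=0)


def read_census(text: str) -> RegionCensus:
    """Inverse of :func:`census_table`."""
    residue_counts: dict[str, int] = {}
    snp_counts = {cat: {} for cat in VariantCategory}
    unmapped: dict[VariantCategory, int] = {}
    context = ""
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        context, kind, cat, region, count = line.split("\t")
        if kind == "residues":
            residue_counts[region] = int(count)
        else:
            category = VariantCategory(cat)
            if region == "unmapped":
                unmapped[category] = int(count)
            else:
                snp_counts[category][region] = int(count)
    return RegionCensus(context=context, residue_counts=residue_counts,
                        snp_counts=snp_counts, unmapped=unmapped)


def load_run(poses_text: str, manifest: dict) -> DockingRun:
    """Rebuild a :class:`DockingRun` from its poses table and manifest."""
    import numpy as np

    from .docking import Pose
    from .energy import EnergyScore

    poses, energies = [], []
    weights = tuple(manifest.get("weights", (1.0, 1.0, 0.1)))
    for line in poses_text.splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        rot = np.array([float(v) for v in f[2:11]]).reshape(3, 3)
        trans = np.array([float(v) for v in f[11:14]])
        poses.append(Pose(rotation=rot, translation=trans,
                          shape_score=float(f[14]), rank=int(f[0]),
                          rotation_index=int(f[1])))
        if f[15]:
            energies.append(EnergyScore(
                electrostatics=float(f[15]), van_der_waals=float(f[16]),
                desolvation=float(f[17]), weights=weights))
    return DockingRun(
        receptor_id=manifest.get("receptor_id", ""),
        ligand_id=manifest.get("ligand_id", ""),
        spacing=manifest["spacing"],
        n_rotations=manifest["n_rotations"],
        n_keep=manifest["n_keep"],
        seed=manifest["seed"],
        ligand_center=np.array(manifest["ligand_center"]),
        poses=poses, energies=energies,
        config=manifest.get("config", {}),
    )
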