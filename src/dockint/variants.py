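"""Missense variant tables, sequence-structure numbering, and the census.

Variants arrive in the UniProt *humsavar* dialect (gene, accession, FTId,
``p.Xaa123Xaa`` substitution, category, phenotype) with the 2014
three-category vocabulary Disease / Polymorphism / Unclassified.  Each
variant position is carried from UniProt sequence numbering to structure
numbering through a global sequence alignment, then annotated with its
structural location by combining complex structures (where available)
with docking-based extended interface predictions.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .classify import LocationLabel
from .nip import NIP_HOTSPOT_CUTOFF, NIPProfile
from .sasa import ASAProfile
from .structures import THREE_TO_ONE, ResidueKey, StructureModel

__all__ = [
    "VariantCategory",
    "Evidence",
    "VariantRecord",
    "VariantAnnotation",
    "NumberingMap",
    "AlignmentError",
    "RegionCensus",
    "parse_variant_table",
    "build_numbering_map",
    "annotate_variants",
    "census",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class VariantCategory(enum.Enum):
    DISEASE = "Disease"
    POLYMORPHISM = "Polymorphism"
    UNCLASSIFIED = "Unclassified"


# humsavar vocabulary -> category; the post-2014 likely-pathogenic /
# likely-benign tokens are accepted only when explicitly enabled.
CATEGORY_TOKENS = {
    "Disease": VariantCategory.DISEASE,
    "Polymorphism": VariantCategory.POLYMORPHISM,
    "Unclassified": VariantCategory.UNCLASSIFIED,
}
MODERN_CATEGORY_TOKENS = {
    "LP/P": VariantCategory.DISEASE,
    "LB/B": VariantCategory.POLYMORPHISM,
    "US": VariantCategory.UNCLASSIFIED,
}


class Evidence(enum.Enum):
    STRUCTURE = "structure"
    DOCKING = "docking"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class VariantRecord:
    protein_accession: str
    position: int
    wt_aa: str
    mut_aa: str
    category: VariantCategory
    phenotype_text: str = ""
    gene: str = ""
    ftid: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.wt_aa == self.mut_aa:
            raise ValueError("silent substitution is not a missense variant")


@dataclass
class VariantAnnotation:
    record: VariantRecord
    location: LocationLabel | None       # None = unmapped
    hotspot: bool
    evidence: Evidence

    def __post_init__(self) -> None:
        if self.hotspot and self.location is not LocationLabel.INTERFACE:
            raise ValueError("hot-spot variants must be interface variants")
        if (self.evidence is Evidence.NONE) != (self.location is None):
            raise ValueError("evidence NONE exactly when unmapped")


class AlignmentError(ValueError):
    """Sequence-structure alignment below the identity threshold."""

    def __init__(self, message: str, alignment=None):
        super().__init__(message)
        self.alignment = alignment


@dataclass
class NumberingMap:
    """Injective map from UniProt sequence position to structure residue."""

    accession: str
    source_id: str
    chain_id: str
    mapping: dict[int, ResidueKey]
    identity: float

    def inverse(self) -> dict[ResidueKey, int]:
        return {v: k for k, v in self.mapping.items()}


def _parse_substitution(token: str) -> tuple[str, int, str] | None:
    if not token.startswith("p."):
        return None
    body = token[2:]
    wt3, rest = body[:3], body[3:]
    digits = ""
    for ch in rest:
        if ch.isdigit():
            digits += ch
        else:
            break
    mut3 = rest[len(digits):].upper()
    wt3 = wt3.upper()
    if wt3 not in THREE_TO_ONE or mut3 not in THREE_TO_ONE or not digits:
        return None
    return THREE_TO_ONE[wt3], int(digits), THREE_TO_ONE[mut3]


def parse_variant_table(text: str, strict: bool = False,
                        allow_modern_vocabulary: bool = False
                        ) -> list[VariantRecord]:
    """Parse humsavar-dialect text into :class:`VariantRecord` objects.

    Unparseable substitutions and silent substitutions are skipped with a
    warning (or raise, in strict mode).  Header and non-variant lines are
    ignored.
    """
    vocab = dict(CATEGORY_TOKENS)
    if allow_modern_vocabulary:
        vocab.update(MODERN_CATEGORY_TOKENS)
    records: list[VariantRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 5:
            continue
        sub_idx = next((i for i, t in enumerate(tokens)
                        if t.startswith("p.")), None)
        if sub_idx is None or sub_idx + 1 >= len(tokens):
            continue
        category = vocab.get(tokens[sub_idx + 1])
        if category is None:
            continue
        parsed = _parse_substitution(tokens[sub_idx])
        if parsed is None:
            msg = f"line {lineno}: unparseable substitution {tokens[sub_idx]!r}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        wt, pos, mut = parsed
        if wt == mut:
            msg = f"line {lineno}: silent substitution {tokens[sub_idx]!r}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        rest = tokens[sub_idx + 2:]
        if rest and (rest[0] == "-" or rest[0].startswith("rs")):
            rest = rest[1:]
        records.append(VariantRecord(
            protein_accession=tokens[1] if sub_idx >= 3 else tokens[0],
            position=pos, wt_aa=wt, mut_aa=mut, category=category,
            phenotype_text=" ".join(rest),
            gene=tokens[0] if sub_idx >= 3 else "",
            ftid=tokens[2] if sub_idx >= 3 else "",
        ))
    return records


def build_numbering_map(uniprot_sequence: str, structure: StructureModel,
                        accession: str = "", chain_id: str | None = None,
                        min_identity: float = 0.95) -> NumberingMap:
    """Align the structure-derived chain sequence to the full sequence.

    Only aligned, identical positions enter the map, so the mapped
    residue's amino acid always equals the sequence's.  Identity is the
    fraction of identical columns over the aligned (covered) span; maps
    below ``min_identity`` are rejected with the alignment attached for
    inspection.
    """
    if chain_id is None:
        chain_id = structure.residues[0].chain_id
    struct_seq, keys = structure.sequence(chain_id)
    if not struct_seq:
        raise ValueError(f"chain {chain_id!r} has no residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(uniprot_sequence, struct_seq)[0]
    mapping: dict[int, ResidueKey] = {}
    n_aligned = 0
    n_identical = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            sp = t0 + off          # 0-based sequence position
            qp = q0 + off          # 0-based structure-sequence position
            n_aligned += 1
            if uniprot_sequence[sp] == struct_seq[qp]:
                n_identical += 1
                mapping[sp + 1] = keys[qp]
    identity = n_identical / n_aligned if n_aligned else 0.0
    if identity < min_identity:
        raise AlignmentError(
            f"sequence-structure identity {identity:.3f} below "
            f"{min_identity} for {accession or structure.source_id}",
            alignment=aln)
    return NumberingMap(accession=accession, source_id=structure.source_id,
                        chain_id=chain_id, mapping=mapping, identity=identity)


def annotate_variants(
    variants: list[VariantRecord],
    maps: dict[str, list[NumberingMap]],
    structure_labels: dict[str, dict[ResidueKey, LocationLabel]] | None = None,
    docking_profiles: dict[str, NIPProfile] | None = None,
    rasa_profiles: dict[str, ASAProfile] | None = None,
    core_cutoff: float = 0.1,
    strict: bool = False,
) -> list[VariantAnnotation]:
    """Assign each variant a structural location and its evidence source.

    A variant is INTERFACE when its residue is at an interface in *any*
    complex structure or inside an extended docking patch in *any*
    docking profile; otherwise core / non-interacting surface by averaged
    rASA.  A variant is a hot-spot when additionally NIP >= 0.2 for some
    docking partner.  Wild-type mismatches and positions outside every
    structure are reported as unmapped (strict mode raises on mismatch).
    """
    structure_labels = structure_labels or {}
    docking_profiles = docking_profiles or {}
    rasa_profiles = rasa_profiles or {}
    out: list[VariantAnnotation] = []
    for var in variants:
        mapped: list[tuple[str, ResidueKey]] = []
        mismatched = False
        for nm in maps.get(var.protein_accession, []):
            key = nm.mapping.get(var.position)
            if key is None:
                continue
            if THREE_TO_ONE.get(key.name) != var.wt_aa:
                mismatched = True
                continue
            mapped.append((nm.source_id, key))
        if not mapped:
            if mismatched:
                msg = (f"{var.protein_accession} p.{var.wt_aa}{var.position}"
                       f"{var.mut_aa}: wild type disagrees with structure")
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
            out.append(VariantAnnotation(var, None, False, Evidence.NONE))
            continue

        iface_structure = any(
            structure_labels.get(sid, {}).get(key) is LocationLabel.INTERFACE
            for sid, key in mapped)
        iface_docking = False
        hot_by_nip = False
        covered_docking = False
        for sid, key in mapped:
            prof = docking_profiles.get(sid)
            if prof is None:
                continue
            if key in prof.residues:
                covered_docking = True
            if key in prof.extended_interface:
                iface_docking = True
            if prof.nip_dict().get(key, -np.inf) >= NIP_HOTSPOT_CUTOFF:
                hot_by_nip = True
        covered_structure = any(key in structure_labels.get(sid, {})
                                for sid, key in mapped)

        if iface_structure or iface_docking:
            location = LocationLabel.INTERFACE
            src_s, src_d = iface_structure, iface_docking
        else:
            rasas = [rasa_profiles[sid].rasa_dict()[key]
                     for sid, key in mapped
                     if sid in rasa_profiles
                     and key in rasa_profiles[sid].rasa_dict()]
            if rasas:
                buried = float(np.mean(rasas)) < core_cutoff
            else:
                buried = any(
                    structure_labels.get(sid, {}).get(key) is LocationLabel.CORE
                    for sid, key in mapped)
            location = (LocationLabel.CORE if buried
                        else LocationLabel.NON_INTERFACE_SURFACE)
            src_s = covered_structure or bool(rasas)
            src_d = covered_docking
        if src_s and src_d:
            evidence = Evidence.BOTH
        elif src_d:
            evidence = Evidence.DOCKING
        else:
            evidence = Evidence.STRUCTURE
        hotspot = hot_by_nip and location is LocationLabel.INTERFACE
        out.append(VariantAnnotation(var, location, hotspot, evidence))
    return out


@dataclass
class RegionCensus:
    """Counts of residues and variants by structural location (one context).

    ``residue_counts`` keys: total, core, interface, non_interface,
    hotspot, hotspot_at_interface.  ``snp_counts`` maps each category to
    counts for core, interface, non_interface and interface_hotspot.
    """

    context: str
    residue_counts: dict[str, int]
    snp_counts: dict[VariantCategory, dict[str, int]]
    unmapped: dict[VariantCategory, int] = field(default_factory=dict)
    n_proteins: int = 0
    n_proteins_with_snp: int = 0

    def __post_init__(self) -> None:
        rc = self.residue_counts
        if rc.get("hotspot_at_interface", 0) > rc.get("interface", 0):
            raise ValueError("interface hot-spot residues exceed interface")
        for cat, counts in self.snp_counts.items():
            if counts.get("interface_hotspot", 0) > counts.get("interface", 0):
                raise ValueError(
                    f"{cat}: interface hot-spot variants exceed interface")

    def snp_total(self, category: VariantCategory) -> int:
        c = self.snp_counts[category]
        return c["core"] + c["interface"] + c["non_interface"]

    @property
    def total_snps(self) -> int:
        return sum(self.snp_total(c) for c in self.snp_counts)


def census(annotations: list[VariantAnnotation],
           residue_labels: dict[ResidueKey, LocationLabel],
           hotspot_residues: set[ResidueKey] | None = None,
           context: str = "") -> RegionCensus:
    """Tally residues and annotated variants by location and category."""
    hotspot_residues = hotspot_residues or set()
    rc = {"total": len(residue_labels), "core": 0, "interface": 0,
          "non_interface": 0, "hotspot": len(hotspot_residues),
          "hotspot_at_interface": 0}
    for key, lab in residue_labels.items():
        if lab is LocationLabel.CORE:
            rc["core"] += 1
        elif lab is LocationLabel.INTERFACE:
            rc["interface"] += 1
            if key in hotspot_residues:
                rc["hotspot_at_interface"] += 1
        else:
            rc["non_interface"] += 1

    snp: dict[VariantCategory, dict[str, int]] = {
        cat: {"core": 0, "interface": 0, "non_interface": 0,
              "interface_hotspot": 0}
        for cat in VariantCategory
    }
    unmapped = {cat: 0 for cat in VariantCategory}
    for ann in annotations:
        cat = ann.record.category
        if ann.location is None:
            unmapped[cat] += 1
        elif ann.location is LocationLabel.CORE:
            snp[cat]["core"] += 1
        elif ann.location is LocationLabel.INTERFACE:
            snp[cat]["interface"] += 1
            if ann.hotspot:
                snp[cat]["interface_hotspot"] += 1
        else:
            snp[cat]["non_interface"] += 1
    return RegionCensus(context=context, residue_counts=rc, snp_counts=snp,
                        unmapped=unmapped)
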