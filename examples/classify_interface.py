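"""Classify the residues of a two-body complex.

Builds a synthetic complex with a designed 6-residue interface per body,
computes per-residue solvent accessibility on each unbound subunit, and
partitions residues into core (rASA < 0.1), interface (any atom within
10 A of the partner) and non-interacting surface.
"""

from collections import Counter

from dockint import StructureModel, classify_residues, compute_asa
from dockint.fixtures import ToyComplexSpec, make_toy_complex

toy = make_toy_complex(ToyComplexSpec(n_residues=30, interface_size=6,
                                      seed=1))
cplx = StructureModel.merge(toy.receptor, toy.ligand_docked)
labels = classify_residues(
    [compute_asa(toy.receptor), compute_asa(toy.ligand_docked)],
    [(cplx, {"B"}), (cplx, {"A"})])

counts = Counter(lab.value for lab in labels.values())
print("residues per class:", dict(counts))
interface = sorted(str(k) for k, v in labels.items()
                   if v.value == "interface")
print("interface residues:", ", ".join(interface))
print()
print("The 12 interface residues are exactly the two designed caps; the")
print("pseudo-atom bodies are small, so nothing is buried enough to be core.")
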