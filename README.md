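# dockint

Docking-based prediction of protein–protein interfaces and structural
characterization of missense variants (nsSNPs).

## The problem

Most human protein–protein interactions have no experimentally solved
complex structure, so a missense variant can rarely be placed at — or
excluded from — a binding interface directly. `dockint` implements a
pipeline for exactly this situation: when only the individual subunit
structures are available, rigid-body docking of the two partners is used
to predict the interface, and variants are then classified against the
predicted (or, where available, observed) interfaces. The target users
are structural bioinformaticians characterizing disease variants across
interaction networks.

## The method

1. **Residue classification.** Per-residue solvent-accessible surface
   area (Shrake–Rupley, probe 1.4 Å) is divided by a residue-type
   reference maximum to give the relative accessibility rASA. Residues
   with rASA < 0.1 (averaged over all structures covering them) are
   *core*; exposed residues with any atom within 10 Å of a partner atom
   in a complex are *interface*; the rest are *non-interacting surface*.

2. **Docking-based interface prediction.** Rigid-body poses are sampled
   by FFT shape correlation on cubic grids and rescored with a weighted
   sum of Coulomb electrostatics (ε(r) = 4r, per-pair truncation),
   capped 6-12 van der Waals, and an atomic-solvation desolvation term.
   For each residue *i* the averaged buried surface over the 100
   lowest-energy poses is

       ABS_i = (ASA_unbound,i − ⟨ASA_i⟩_poses) / ASA_unbound,i

   normalized per protein to the **normalized interface propensity**

       NIP_i = (ABS_i − mean ABS) / (max ABS − mean ABS).

   Residues with NIP ≥ 0.2 are predicted binding **hot-spots**, and the
   **extended interface patch** adds every surface residue (rASA > 0.1)
   within 10 Å of a hot-spot.

3. **Variant mapping and enrichment.** humsavar-dialect variant tables
   (Disease / Polymorphism / Unclassified) are mapped from UniProt
   numbering onto structures by global alignment, each variant is
   assigned core / interface / non-interacting surface (interface if
   *any* complex structure or *any* docking patch says so), and regional
   preference is quantified by observed/expected ratios and odds ratios

       OR_ij = [P_i/(1−P_i)] / [P_j/(1−P_j)],   P_i = n_i / N_i,

   with two-tailed Fisher exact p-values, where n_i counts variants and
   N_i residues in region *i*.

## Worked example

`examples/census_enrichment.py` pushes the packaged six-disease
interaction-network census through the statistics layer:

```
[structural]
  O/E disease core/interface/surface: 1.68 / 0.70 / 0.75
  OR interface vs non-interacting surface: 0.94 (p = 0.56)
[docking]
  O/E disease core/interface/surface: 1.57 / 0.94 / 0.66
  OR interface vs non-interacting surface: 1.42 (p = 2.2e-06)
[combined]
  O/E disease core/interface/surface: 1.59 / 0.94 / 0.63
  OR interface vs non-interacting surface: 1.51 (p = 7.79e-09)
[combined] hot-spot disease variants: O/E 1.05, OR vs surface 1.68
```

Reading: disease variants are strongly over-represented in the buried
core (O/E 1.6–1.7). With structural data alone they show no interface
preference (OR 0.94, not significant) — an artefact of missing complex
structures. Once docking models fill in the unseen interfaces, a clear
and significant preference for interfaces over the rest of the surface
emerges (OR 1.42–1.51), strongest for predicted hot-spot positions
(OR 1.68).

`examples/dock_and_predict.py` runs the docking pipeline on a synthetic
complex with a designed 6-residue interface:

```
poses scored: 8000, NIP from 100 lowest-energy poses
hot-spots (9 residues):  sensitivity 0.67, precision 0.44
extended patch (20 residues): sensitivity 1.00, precision 0.30
```

The other examples cover residue classification, variant mapping, and
the multi-complex recovery benchmark.

## Command line

A thin CLI wraps the library:

```sh
dockint simulate toy-complex --residues 30 --interface 6 --seed 1 -o fix/
dockint dock --receptor fix/receptor.pdb --ligand fix/ligand.pdb \
    --rotations 100 --spacing 2.0 --seed 1 -o run/
dockint nip --run run/ --receptor fix/receptor.pdb \
    --ligand fix/ligand.pdb -o nip.tsv
dockint classify --complex complex.pdb --receptor-chains A \
    --ligand-chains B -o labels.tsv
dockint census --packaged table2 --context combined -o census.tsv
dockint stats --census census.tsv
```

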