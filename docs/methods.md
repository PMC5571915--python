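# Methods

This note records the models implemented by `dockint`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical corner cases.

## Solvent accessibility and residue classification

Per-atom accessible surface area uses the Shrake–Rupley point method
with a deterministic Fibonacci-spiral point set (default 960 points per
atom, probe radius 1.4 Å). Van der Waals radii are a packaged element
table (C 1.70, N 1.55, O 1.52, S 1.80 Å); unknown elements fall back to
1.70 Å with a warning. Relative accessibility divides the per-residue
sum by the Tien et al. (2013) theoretical maxima (table id
`tien2013-theoretical`, recorded on every profile). Absolute ASA values
therefore carry implementation constants — a different radii set or
point count shifts them by a few percent — and the stable contract is
the thresholded classification, not the raw areas. The implementation is
cross-checked in the tests against closed-form sphere and two-sphere cap
areas (within 2 % at 960 points) and against an independent
implementation with matched radii.

Classification: core iff mean rASA < 0.1 over all structures containing
the residue (averaging resolves conflicting core/exposed calls between
structures); exposed residues are interface iff any atom lies within
10 Å of any partner atom in any supplied complex (all atoms, not CA
only); everything else is non-interacting surface. Hydrogens, waters,
HETATM records and alternate conformers other than blank/'A' are
discarded at parse time; non-standard residues map to a standard parent
where one exists (MSE→MET etc.), otherwise they are skipped with a
warning.

## Docking

Shape sampling follows the grid-correlation scheme: both molecules are
discretized on cubic grids (default spacing 1.2 Å for protein-sized
inputs; the synthetic benchmark uses 2.0 Å) and the score of a relative
translation is the grid cross-correlation, computed for all translations
at once by FFT. Cell values are assigned from the signed distance to the
van der Waals surface: receptor cells inside the surface carry a −15
penalty and cells in a shell of configurable width just outside the
surface (default 1.5 Å; 3.0 Å in the benchmark, matched to its 4 Å cap
separation) carry +1; ligand cells inside the surface carry +1. Placing
the +1 layer outside the surface rather than on the outermost occupied
cells keeps the scheme meaningful for arbitrarily thin bodies — a
two-atom-deep pseudo-protein has no "interior" cells under the classic
assignment, which would leave interpenetration unpenalized. On coarse
grids the cell nearest each atom centre is always marked occupied so
single atoms register.

Rotations are a seeded quasi-uniform sample of SO(3) with the identity
always included (so a fixture supplied in its docked orientation is
reachable at any sample size); per rotation the top-`k` correlation
cells become candidate translations, and the global candidate list is
cut to `n_keep` by shape score with a deterministic (rotation, cell)
tie-break. All candidates are rescored; no pre-rescoring filter is
applied.

The energy of a pose is

    E = w_e · E_elec + w_d · E_desolv + w_v · E_vdw,  (w = 1.0, 1.0, 0.1)

with, summed over intermolecular atom pairs within 12 Å:

* electrostatics: 332 q_i q_j / (4 r²) — Coulomb with the
  distance-dependent dielectric ε(r) = 4r — truncated per pair to ±1;
* van der Waals: ε_LJ [(s/r)¹² − 2(s/r)⁶] with s = r_i + r_j and
  ε_LJ = 0.1, repulsion capped at +1 per pair so clashes cost a bounded
  amount rather than raising errors;
* desolvation: per-element atomic solvation parameters (C −0.010,
  S −0.012, N +0.006, O +0.009 kcal mol⁻¹ Å⁻²) times the area buried on
  complexation, estimated by the pairwise spherical-cap overlap of
  probe-expanded spheres, clamped per atom at its full sphere.

Charges are coarse formal charges (ARG/LYS +1, ASP/GLU −1, HIS +0.1)
spread over side-chain atoms; explicit per-atom charges can be supplied
for fixtures. These functional forms mirror the published
electrostatics + desolvation + van der Waals rescoring composition, but
the original constants are not recoverable, so every constant is
config-exposed and recorded in the run manifest; the ranking, not the
absolute energies, is the contract.

## NIP, hot-spots and extended patches

ABS_i = (ASA_unbound,i − mean over the 100 lowest-energy poses of
ASA_i) / ASA_unbound,i, with ABS = 0 where the unbound ASA is zero.
Per-pose ASA is recomputed exactly (same Shrake–Rupley settings) on the
assembled pose. The normalization to NIP is the affine map sending the
mean ABS to 0 and the maximum to 1; a flat ABS profile maps to all-zero
NIP, hence no hot-spots at any positive cutoff. This map is a design
choice — only the existence of a normalization is fixed by the method's
description, and the chosen map is consistent with NIP values spanning
negative values to 1. Hot-spots are residues with NIP ≥ 0.2 (boundary
inclusive); the extended patch adds surface residues (rASA > 0.1) whose
minimum inter-atomic distance to a hot-spot is ≤ 10 Å, the same metric
as the classification contact rule. For proteins with several partners,
hot-spot and extended-patch flags are unioned over partners.

## Variant mapping

humsavar-dialect tables are parsed tolerantly: unparseable or silent
substitutions are skipped with a warning (strict mode raises). The 2014
three-category vocabulary is canonical; the newer LP/P–LB/B–US tokens
are accepted behind a flag. Sequence-to-structure numbering uses global
alignment (match 1, mismatch −1, gap open −5, extend −0.5); only
aligned identical positions enter the map, and maps with identity below
0.95 over the aligned span are rejected with the alignment attached.
Wild-type mismatches between a variant and the mapped residue leave the
variant unmapped rather than failing, since real PDB entries carry
engineered point mutations. A variant is interface if any complex
structure or any docking patch places it there (this union is why a
combined census is not the sum of its parts); otherwise core vs surface
is decided by the averaged rASA; hot-spot status requires NIP ≥ 0.2 for
some partner *and* interface location. Unmapped variants are excluded
from location counts and reported separately.

## Statistics

O/E = (variants in region / all variants) / (residues in region / all
residues). The odds ratio uses per-residue variant rates P = n/N and
equals the cross-product form (n_i(N_j−n_j))/(n_j(N_i−n_i)); zero cells
get the Haldane–Anscombe +0.5 correction with an explicit flag. The
two-tailed p-value is Fisher's exact test, chosen because it is exact
and reproducible where the original analysis only names an unnamed
two-tailed procedure; at the table sizes involved any reasonable
two-tailed test agrees on significance. Confidence intervals are Wald
intervals on the log odds. Sensitivity TP/(TP+FN) and precision
TP/(TP+FP) report `None`, never 0, when undefined. The random baseline
samples ⌊fraction·n⌉ surface residues uniformly without replacement from
a canonically ordered set, so it is seed-reproducible.

## Synthetic data

The toy complex generator builds two frustum-shaped pseudo-atom bodies
(one backbone and one side-chain sphere per residue, all carbon, 5 Å
lattice, 7 Å between layers) whose cap layers — k residues each, 2×3
for the default k = 6 — meet at a 4 Å gap in the designed pose. Layers
widen with depth so facial contact is only possible cap-to-cap, and the
7 Å layer recession guarantees that exactly the cap residues satisfy
the 10 Å interface rule; the generator verifies this by running the
classifier on the assembled complex and refuses to emit a fixture that
fails. Caps carry complementary formal charges (ARG facing GLU) so that
energy rescoring concentrates the low-energy ensemble at the designed
interface. The unbound ligand placement is a seeded random rigid motion;
everything is a pure function of (spec, seed) and serializes to
byte-identical PDB text.

What this emulates: the logical structure of the real task — unbound
subunits, an unknown but recoverable interface, energy-funneled pose
ensembles, variants with a planted regional bias. What it does not:
real fold geometry, side-chain packing, flexibility, crystallographic
artefacts, or realistic charge distributions. Passing the benchmark
therefore shows the pipeline's machinery is correct and discriminative
under controlled conditions, not that its success rates transfer to
real proteomes.

The variant fixture plants disease variants as independent per-residue
Bernoulli draws on interface vs non-interacting-surface residues, with
the two rates solved (by bracketed root finding) so the planted odds
ratio and the expected total count are hit exactly in expectation;
polymorphisms and unclassified variants are uniform. Counts are bounded
by residue counts by construction, matching the contingency invariants.

## Benchmark problem sizes

The packaged benchmark protocol docks 20 complexes of 30 residues per
body with 100 rotations, 2.0 Å grids, 120 translations kept per
rotation, 8 000 candidates rescored, and NIP over the 100 lowest-energy
poses — about six seconds per complex on one CPU, chosen so the full
benchmark and test suite run comfortably on a laptop. The planted-OR
recovery study uses 200 replicates of 500 disease variants on a
2 000 + 2 000-residue label universe per target odds ratio.

## Known limitations

* Energy constants are package defaults, not fitted values; rankings on
  real proteins will differ from any published scoring implementation.
* The desolvation burial model is a pairwise approximation and
  overcounts in dense multi-atom contacts; it is clamped per atom but
  not self-consistent.
* The NIP normalization is per-protein and scale-free; proteins whose
  low-energy ensemble is diffuse produce weak, noisy hot-spot calls.
* Numbering reconciliation assumes one UniProt sequence per accession
  and ignores insertion-code-level conflicts beyond exact key identity.
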