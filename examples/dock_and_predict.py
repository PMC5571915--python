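"""Predict an interface by docking, without the complex structure.

Starting from the two *unbound* subunits of a synthetic complex, samples
rigid-body poses by FFT shape correlation, rescores them with the
electrostatics + desolvation + van der Waals function, computes NIP over
the 100 lowest-energy poses, calls hot-spots (NIP >= 0.2) and grows the
extended interface patch, then compares against the designed interface.
"""

from dockint import (
    EnergyParams,
    evaluate_prediction,
    generate_poses,
    nip_from_run,
    rescore,
)
from dockint.fixtures import ToyComplexSpec, make_toy_complex

toy = make_toy_complex(ToyComplexSpec(seed=1))
run = generate_poses(toy.receptor, toy.ligand, n_rotations=100, spacing=2.0,
                     n_keep=8000, seed=1, top_per_rotation=120,
                     surface_thickness=3.0)
run = rescore(toy.receptor, toy.ligand, run, EnergyParams())
profile = nip_from_run(toy.receptor, toy.ligand, run, side="receptor")

universe = set(toy.receptor.residues)
hot = evaluate_prediction(profile.hotspots, toy.truth_receptor, universe)
ext = evaluate_prediction(profile.extended_interface, toy.truth_receptor,
                          universe)
print(f"poses scored: {len(run.poses)}, NIP from "
      f"{profile.n_poses_used} lowest-energy poses")
print(f"hot-spots ({len(profile.hotspots)} residues):  "
      f"sensitivity {hot.sensitivity:.2f}, precision {hot.precision:.2f}")
print(f"extended patch ({len(profile.extended_interface)} residues): "
      f"sensitivity {ext.sensitivity:.2f}, precision {ext.precision:.2f}")
print()
print("Raw hot-spots are precise but sparse; extending the patch to surface")
print("residues within 10 A trades precision for the sensitivity needed to")
print("screen variants against predicted interfaces.")
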