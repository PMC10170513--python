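"""Evaluate the 5-CV set on the pseudo-molecular cage/ligand complex.

Builds the reproducible toy complex, pulls the rigid ligand along its exit
axis, and prints the five collective variables (pulling distance, angle,
dihedral, binding-site RMSD, ligand RMSD) plus the geometric unbound flag
at each displacement.  The unbound criterion — no receptor atom within
5 Å of any ligand atom — flips once the ligand clears the cage.
"""

import metadrt as m

complex_, specs = m.generate_pseudo_complex(seed=3)

print(f"{'d (Å)':>6} " + " ".join(f"{s.name:>15}" for s in specs) + "  unbound")
for d in [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0]:
    frame = complex_.frame(d)
    values = m.evaluate_cvs(frame, specs)
    unbound = m.is_unbound(frame, complex_.ligand_group, complex_.receptor_group)
    print(f"{d:6.1f} " + " ".join(f"{v:15.3f}" for v in values) + f"  {unbound}")

print(
    "\nThe pulling distance (cv1) grows linearly with the displacement, the\n"
    "angular CVs drift as the exit direction rotates relative to the anchor\n"
    "COMs, and both RMSDs track how far the configuration has left the bound\n"
    "reference.  The ligand counts as unbound beyond ~10 Å displacement."
)
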