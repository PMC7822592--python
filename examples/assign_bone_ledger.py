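"""Assign the packaged bone-homogenate intact-mass ledger.

Loads the seven deconvoluted neutral masses measured in mouse bone
homogenate, assigns each to its most probable modification composition at
10 ppm, and aggregates the relative abundances into the glycosylated vs
non-glycosylated split.
"""

from ocnforms import aggregate, assign_masses, builtin_peaklist, builtin_protein
from ocnforms.assignment import modification_label, oligosaccharide_label

mouse = builtin_protein("mouse")
observations = builtin_peaklist("bone_homogenate")
assigned = assign_masses(observations, mouse, tolerance_ppm=10.0)

print(f"{'mass (Da)':>11s}  {'%':>6s}  {'ppm':>6s}  modification / oligosaccharide")
for a in assigned:
    obs = a.observation
    print(f"{obs.neutral_mass:11.4f}  {obs.relative_abundance:6.2f}  "
          f"{a.best_ppm:+6.2f}  {modification_label(a.best)}"
          f"  [{oligosaccharide_label(a.best)}]")

table = aggregate(assigned)
print("\nclass totals (%):")
print(table.rows.to_string(index=False))
print("\nAlmost all osteocalcin extracted from bone carries the core-1 "
      "O-glycan; the remainder is carboxylated but unglycosylated.")
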