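"""Theoretical proteoform masses of mature mouse osteocalcin.

Builds the packaged 46-residue mouse chain and prints the monoisotopic
masses of its reference proteoforms: the fully carboxylated (3x Gla),
disulfide-formed protein, the uncarboxylated base, and the core-1
glycoforms, together with the 5+ m/z of the glycan + 3 Gla form.
"""

from ocnforms import ProteoformComposition, builtin_protein, charge_mz, monoisotopic_mass

mouse = builtin_protein("mouse")
print(f"protein: {mouse.id} ({len(mouse)} aa), gla sites {mouse.gla_sites}, "
      f"disulfide {mouse.disulfide_bonds[0]}")

forms = {
    "uncarboxylated base (S-S formed)": {},
    "fully carboxylated (3x Gla)": {"Gla": 3},
    "glycan HexNAc-Hex-NANA, 0 Gla": {"HexNAc": 1, "Hex": 1, "NeuAc": 1},
    "glycan HexNAc-Hex-2xNANA, 0 Gla": {"HexNAc": 1, "Hex": 1, "NeuAc": 2},
    "glycan HexNAc-Hex-2xNANA + 2x Gla": {"HexNAc": 1, "Hex": 1, "NeuAc": 2, "Gla": 2},
    "glycan HexNAc-Hex-NANA + 3x Gla": {"HexNAc": 1, "Hex": 1, "NeuAc": 1, "Gla": 3},
}
for label, counts in forms.items():
    mass = monoisotopic_mass(mouse, ProteoformComposition(counts))
    print(f"  {label:36s} {mass:12.4f} Da")

glyco_3gla = monoisotopic_mass(
    mouse, ProteoformComposition({"HexNAc": 1, "Hex": 1, "NeuAc": 1, "Gla": 3})
)
print(f"5+ m/z of the glycan + 3x Gla form: {charge_mz(glyco_3gla, 5):.5f}")
print("Each Gla adds one CO2 (+43.98983 Da); the formed disulfide removes "
      "2.01565 Da; glycan units add 203.079/162.053/291.095 Da.")
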