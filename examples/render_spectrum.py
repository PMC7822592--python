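"""Render a synthetic profile-mode spectrum of a proteoform mixture.

Builds a two-component mixture (mono-sialylated glycoform with 3 Gla, and
the carboxylated unglycosylated form), renders its isotope envelopes at
charge 5+ with Orbitrap-like resolving power, and reports the base peaks.
"""

from ocnforms import (
    MixtureTruth,
    ProteoformComposition,
    builtin_protein,
    charge_mz,
    monoisotopic_mass,
    simulate_spectrum,
)

mouse = builtin_protein("mouse")
mix = MixtureTruth(
    components=(
        (ProteoformComposition({"HexNAc": 1, "Hex": 1, "NeuAc": 1, "Gla": 3}), 0.7),
        (ProteoformComposition({"Gla": 3}), 0.3),
    ),
    seed=0,
)
spectrum = simulate_spectrum(mix, mouse, charges=(5,), resolution_fwhm=70000,
                             mz_range=(1040.0, 1200.0))

for comp, weight in mix.components:
    mono_mz = charge_mz(monoisotopic_mass(mouse, comp), 5)
    near = spectrum[(spectrum["mz"] - mono_mz).abs() < 1.5]
    peak = near.loc[near["intensity"].idxmax()]
    print(f"weight {weight:.1f}  monoisotopic 5+ m/z {mono_mz:10.5f}  "
          f"base peak near {peak['mz']:10.5f} (intensity {peak['intensity']:.3f})")

print(f"\ngrid points: {len(spectrum)}; isotopologue spacing at 5+ is "
      f"~{1.00235 / 5:.5f} m/z (one neutron over five charges)")
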