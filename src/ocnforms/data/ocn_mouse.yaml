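# Mature mouse osteocalcin site inventory (1-based mature-chain numbering).
# gla_sites: glutamates carboxylated by the vitamin-K-dependent carboxylase.
# glycosites: all Ser/Thr residues; S8 is the established O-glycosylation
# site in osteoblasts, but purified protein can carry a second glycan chain.
disulfide_bonds:
  - [19, 25]
gla_sites: [13, 17, 20]
glycosites: [5, 8, 15, 29, 36, 45]
# Theoretical mass of the fully carboxylated (3x Gla), disulfide-formed
# form, used to validate the sequence transcription on load.
anchor_mass_da: 5243.45
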