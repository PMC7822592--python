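neutral_mass_da	mass_hi_da	relative_abundance_pct	reported_modification	reported_oligosaccharide	label
5855.6676		0.54	Glycosylation + 2x Gla	HexNAc, Hex, NANA	bone_1
5899.7161		7.43	Glycosylation + 3x Gla	HexNAc, Hex, NANA	bone_2
5915.6386	6135.6796	36.07	Glycosylation + 3x Gla + oxidation + additional unidentified modifications or adduct ions	HexNAc, Hex, NANA	bone_3
6146.7609	6162.7991	5.42	Glycosylation + 2x Gla + additional unidentified modifications	HexNAc, Hex, 2x NANA	bone_4
6190.8061		4.49	Glycosylation + 3x Gla	HexNAc, Hex, 2x NANA	bone_5
6206.8016	6441.7636	45.12	Glycosylation + 3x Gla + oxidation + additional unidentified modifications or adduct ions	HexNAc, Hex, 2x NANA	bone_6
5259.4204		0.93	3x Gla + oxidation	NA	bone_7
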