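neutral_mass_da	mass_hi_da	relative_abundance_pct	reported_modification	reported_oligosaccharide	label
5767.6961		4.80	Glycosylation	HexNAc, Hex, NANA	sup_01
5783.6801		0.25	Glycosylation + oxidation	HexNAc, Hex, NANA	sup_02
5855.6676		4.60	Glycosylation + 2x Gla	HexNAc, Hex, NANA	sup_03
5899.7161		3.16	Glycosylation + 3x Gla	HexNAc, Hex, NANA	sup_04
5915.6386	5968.5796	5.51	Glycosylation + 3x Gla + oxidation + additional unidentified modifications or adduct ions	HexNAc, Hex, NANA	sup_05
6058.7916		24.48	Glycosylation	HexNAc, Hex, 2x NANA	sup_06
6074.7766	6096.7409	2.48	Glycosylation + oxidation	HexNAc, Hex, 2x NANA	sup_07
6102.7681		7.89	Glycosylation + 1x Gla	HexNAc, Hex, 2x NANA	sup_08
6146.7609		23.97	Glycosylation + 2x Gla	HexNAc, Hex, 2x NANA	sup_09
6190.8061	6214.7278	6.72	Glycosylation + 3x Gla + additional unidentified modifications or adduct ions	HexNAc, Hex, 2x NANA	sup_10
5127.4676		3.00	Oxidation	NA	sup_11
5171.4301		1.85	1x Gla + oxidation	NA	sup_12
5199.4446		2.08	2x Gla	NA	sup_13
5215.4296		8.50	2x Gla + oxidation	NA	sup_14
5259.4204		0.66	3x Gla + oxidation	NA	sup_15
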