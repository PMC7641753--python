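# Study library of bulge-loop-inducing conjugates: recognition arms written
# 5'->3' around the peptide attachment point (A* = aminohexyl-modified
# adenosine, pairs as A; abasic dR never pairs). Lengths in angstroms:
# unfolded catalytic peptide 36.5, aminohexyl linker 8.6.
name	arm5	attachment	arm3	peptide	peptide_length_A	linker_length_A
BC2	TGGTGCGAATT	modified_adenosine	GTGGATCGAA	acetyl-[LR]4G-CO2H	36.5	8.6
BC3	TGGTGCGAATT	modified_adenosine	TGGATCGAA	acetyl-[LR]4G-CO2H	36.5	8.6
BC4	TGGTGCGAATT	modified_adenosine	GGATCGAA	acetyl-[LR]4G-CO2H	36.5	8.6
BC5	TGGTGCGAATT	modified_adenosine	GATCGAA	acetyl-[LR]4G-CO2H	36.5	8.6
BC2-a	TGGTGCGAATT	abasic_alpha	GTGGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC2-b	TGGTGCGAATT	abasic_beta	GTGGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC3-a	TGGTGCGAATT	abasic_alpha	TGGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC3-b	TGGTGCGAATT	abasic_beta	TGGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC4-a	TGGTGCGAATT	abasic_alpha	GGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC4-b	TGGTGCGAATT	abasic_beta	GGATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC5-a	TGGTGCGAATT	abasic_alpha	GATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC5-b	TGGTGCGAATT	abasic_beta	GATCGAACACAG	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC5L-a	TGGTGCGAATT	abasic_alpha	GATCGAACACAGGAC	acetyl-[LRLRG]2-CO2H	36.5	8.6
BC5L-b	TGGTGCGAATT	abasic_beta	GATCGAACACAGGAC	acetyl-[LRLRG]2-CO2H	36.5	8.6
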