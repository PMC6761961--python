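gene	type	ds	y_in_corytophanes	stratum_published	anolis_chrom	chicken_chrom	human_chrom	function
NIBANY/FAM129BY	protein-coding	0.42	Yes	1	GL343556	17	9	Family with sequence similarity 129 member B
CAMSAP1Y	protein-coding	0.36	Yes	1	GL343625	17	9	Calmodulin regulated spectrin associated protein 1
Unknown	protein-coding	0.27	Yes	1	NA	NA	NA	Hypothetical zinc finger
EHMT1Y	protein-coding	0.26	Yes	1	GL343556	17	9	Euchromatic histone lysine methyltransferase 1
CACNA1BY	protein-coding	0.24	Yes	1	GL343556	17	9	Calcium voltage-gated channel subunit alpha1 B
AKIY	protein-coding	0.22	No	2	AAWZ02036994	17	9	Adenylate kinase isoenzyme 1
MEGF9Y	protein-coding	0.17	No	2	GL343398	17	9	Multiple EGF like domains 9
RAB14Y	protein-coding	0.11	No	2	AAWZ02036218	17	9	Member RAS oncogene family
HSPA5Y	protein-coding	0.088	No	2	AAWZ02037731	17	9	Heat shock protein family A (Hsp70) member 5
GOLGA2Y	protein-coding	0.083	No	2	GL343763	17	9	Golgin A2
ZBTB34Y	protein-coding	0.069	No	2	GL343502	17	9	Zinc finger and BTB domain containing 34
CCDC183Y	protein-coding	NA	No	2	NA	NA	9	Coiled-coil domain containing 183
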