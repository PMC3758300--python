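characteristic	Calamus	Pseudophoenix	Phoenix	Bismarckia	Elaeis	Cocos
size_bp	157270	157829	158462	158211	156973	154731
lsc_bp	85525	85736	86198	86390	85192	84230
ssc_bp	17595	17587	17712	17459	17639	17391
ir_bp	54150	54506	54552	54362	54142	53110
gc_percent	37.36	37.32	37.23	37.47	37.40	37.44
total_genes	131	131	131	131	131	129
protein_coding_genes	85	85	85	85	85	84
protein_gc_percent	38	38	38	38	38	37
protein_bases_bp	192481	191886	192511	120079	10782	90130
rrna_genes	8	8	8	8	8	8
rrna_gc_percent	55	55	55	55	55	55
rrna_bases_bp	9050	9051	9050	9050	7040	9040
trna_genes	38	38	38	38	38	38
trna_gc_percent	53	53	53	53	53	44
trna_bases_bp	10748	10756	10766	10789	10782	10570
pseudogenes	1	1	1	1	1	2
genes_with_introns	22	22	22	22	22	22
protein_genes_with_introns	14	14	14	14	14	14
trna_with_introns	8	8	8	8	8	8
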