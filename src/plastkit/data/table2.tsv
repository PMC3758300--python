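aa	codon	count	rscu_printed	trna
Phe	UUU	906	1.23
Phe	UUC	564	0.77	trnF-GAA
Leu	UUA	785	0.60
Leu	UUG	556	0.42	trnL-CAA
Leu	CUA	371	0.28	trnL-UAG
Leu	CUC	188	0.14
Leu	CUG	173	0.13
Leu	CUU	551	0.42
Ile	AUA	718	0.64	trnI-CAU
Ile	AUC	487	0.43	trnI-GAU
Ile	AUU	1045	0.93
Met	ATG	613	1.00	trn(f)M-CAU
Val	GUA	517	0.74	trnV-UAC
Val	GUC	188	0.27	trnV-GAC
Val	GUG	190	0.27
Val	GUU	497	0.71
Ser	AGC	104	0.10	trnS-GCU
Ser	AGU	414	0.40
Ser	UCA	440	0.43	trnS-UGA
Ser	UCC	338	0.33	trnS-GGA
Ser	UCG	179	0.17
Ser	UCU	574	0.56
Pro	CCA	312	0.59	trnP-UGG
Pro	CCC	207	0.39
Pro	CCG	131	0.25
Pro	CCU	407	0.77
Thr	ACA	417	0.64	trnT-UGU
Thr	ACC	241	0.37	trnT-GGU
Thr	ACG	149	0.23
Thr	ACU	504	0.77
Ala	GCA	383	0.59	trnA-UGC
Ala	GCC	202	0.31
Ala	GCG	123	0.19
Ala	GCU	586	0.91
Tyr	UAU	769	1.59
Tyr	UAC	196	0.41	trnY-GUA
His	CAC	144	0.45	trnH-GUG
His	CAU	493	1.55
Gln	CAA	668	1.49	trnQ-UUG
Gln	CAG	226	0.51
Asn	AAC	274	0.44	trnN-GUU
Asn	AAU	967	1.56
Lys	AAG	353	0.53
Lys	AAA	988	1.47	trnK-UUU
Asp	GAC	209	0.39	trnD-GUC
Asp	GAU	863	1.61
Glu	GAA	1009	1.49	trnE-UUC
Glu	GAG	346	0.51
Cys	UGC	78	0.48	trnC-GCA
Cys	UGU	245	1.52
Trp	TGG	444	1.00	trnW-CCA
Arg	AGA	512	0.65	trnR-UCU
Arg	AGG	161	0.20
Arg	CGA	345	0.44
Arg	CGC	89	0.11
Arg	CGG	123	0.16
Arg	CGU	344	0.44	trnR-ACG
Gly	GGA	712	0.83	trnG-UCC
Gly	GGC	143	0.17	trnG-GCC
Gly	GGG	276	0.32
Gly	GGU	587	0.68
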