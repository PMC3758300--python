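gene	nt_position	codon_change	codon_position	aa_change	predicted	rtpcr	shared
accD	154	CGG-TGG	1	R-W	1	unedited	0
accD	794	TCG-TTG	2	S-L	0	edited	0
accD	1157	TCA-TTA	2	S-L	1	edited	0
accD	1159	CAT-TAT	1	H-Y	1	unedited	0
accD	1403	CCT-CTT	2	P-L	1	unedited	0
atpA	914	TCA-TTA	2	S-L	1	edited	0
atpA	1148	TCA-TTA	2	S-L	1	partial	0
atpB	1184	TCA-TTA	2	S-L	1	edited	1
atpF	92	CCA-CTA	2	P-L	1	partial	1
atpI	428	CCC-CTC	2	P-L	1	edited	0
atpI	629	TCA-TTA	2	S-L	1	edited	0
ccsA	647	ACT-ATT	2	T-I	1	unedited	0
clpP	82	CAT-TAT	1	H-Y	1	edited	1
clpP	559	CAT-TAT	1	H-Y	1	edited	1
matK	188	TCA-TTA	2	S-L	1	unedited	0
matK	653	CCA-CTA	2	P-L	1	unedited	0
matK	734	TTC-TTT	3	D-F	0	edited	0
matK	919	CAT-TAT	1	H-Y	1	unedited	0
matK	1267	CAC-TAC	1	H-Y	1	edited	0
ndhA	50	TCG-TTG	2	S-L	1	edited	0
ndhA	476	TCA-TTA	2	S-L	1	edited	0
ndhA	566	TCA-TTA	2	S-L	1	edited	0
ndhA	961	CCT-TCT	1	P-S	1	edited	0
ndhA	1073	TCC-TTC	2	S-F	1	unedited	0
ndhB	149	TCA-TTA	2	S-L	1	partial	0
ndhB	467	CCA-CTA	2	P-L	1	edited	0
ndhB	542	ACG-ATG	2	T-M	1	edited	0
ndhB	586	CAT-TAT	1	H-Y	1	edited	0
ndhB	704	TCC-TTC	2	S-F	1	edited	0
ndhB	737	CCA-CTA	2	P-L	0	edited	1
ndhB	830	TCA-TTA	2	S-L	1	edited	0
ndhB	836	TCA-TTA	2	S-L	1	edited	0
ndhB	1112	TCA-TTA	2	S-L	1	edited	0
ndhB	1193	TCA-TTA	2	S-L	1	edited	0
ndhB	1255	CAT-TAT	1	H-Y	1	edited	0
ndhB	1481	CCA-CTA	2	P-L	1	partial	0
ndhD	2	ACG-ATG	2	T-M	1	partial	0
ndhD	59	TCA-TTA	2	S-L	1	edited	0
ndhD	383	TCA-TTA	2	S-L	1	edited	0
ndhD	674	TCG-TTG	2	S-L	1	edited	0
ndhD	947	ACA-ATA	2	T-I	1	edited	0
ndhD	1193	TCA-TTA	2	S-L	1	edited	0
ndhD	1310	TCA-TTA	2	S-L	1	edited	0
ndhF	62	TCA-TTA	2	S-L	1	partial	0
ndhF	290	TCA-TTA	2	S-L	1	partial	0
ndhF	392	TCC-TTC	2	S-F	1	edited	0
ndhF	442	CAT-TAT	1	H-Y	1	edited	0
ndhF	586	CTT-TTT	1	L-F	1	unedited	0
ndhF	1393	CAC-TAC	1	H-Y	1	unedited	0
ndhF	2093	TCC-TTC	2	S-F	1	unedited	0
ndhG	314	ACA-ATA	2	T-I	1	unedited	0
ndhG	347	CCA-CTA	2	P-L	0	edited	0
ndhH	505	CAT-TAT	1	S-L	1	edited	0
ndhH	545	TCT-TTT	2	S-F	0	partial	1
ndhH	726	TAC-TAT	3	Y-Y	0	unedited	0
ndhK	131	TCG-TTG	2	S-L	1	edited	0
ndhK	372	GTC-GTT	3	S-L	0	unedited	0
ndhK	518	ATG-ACG	2	M-T	0	unedited	0
ndhK	677	TCA-TTA	2	S-L	0	unedited	0
petB	418	CGG-TGG	1	R-W	1	edited	1
petB	611	CCA-CTA	2	P-L	1	edited	0
psaI	80	TCT-TTT	2	S-F	1	edited	0
psaI	85	CAT-TAT	1	H-Y	1	edited	0
rpl2	2	ACG-ATG	2	T-M	1	unedited	0
rpl20	26	ACA-ATA	2	T-I	1	unedited	0
rpl20	308	TCA-TTA	2	S-L	1	unedited	0
rpl22	242	TCA-TTA	2	S-L	0	unedited	0
rpl23	71	TCA-TTA	2	S-L	0	partial	1
rpl23	89	TCT-TTT	2	S-F	0	partial	1
rpoA	200	TCT-TTT	2	S-F	0	edited	0
rpoA	368	TCA-TTA	2	S-L	1	edited	0
rpoA	527	TCC-TTC	2	S-F	1	edited	0
rpoA	830	TCA-TTA	2	S-L	1	edited	0
rpoA	887	TCG-TTG	2	S-L	1	unedited	0
rpoB	467	TCG-TTG	2	S-L	1	partial	0
rpoB	545	TCA-TTA	2	S-L	1	edited	0
rpoB	560	TCG-TTG	2	S-L	1	edited	0
rpoB	617	CCG-CTG	2	P-L	1	partial	0
rpoB	1994	TCT-TTT	2	S-F	1	edited	0
rpoB	2420	TCA-TTA	2	S-L	1	partial	0
rpoC1	41	CCA-CTA	2	P-L	1	edited	0
rpoC1	511	CGG-TGG	1	R-W	1	edited	0
rpoC1	617	TCA-TTA	2	S-L	1	edited	0
rpoC1	1663	CAT-TAT	1	H-Y	1	unedited	0
rpoC2	1381	CAT-TAT	1	H-Y	1	unedited	0
rpoC2	2275	CGG-TGG	1	R-W	1	unedited	0
rpoC2	2309	TCG-TTG	2	S-L	1	edited	0
rps2	134	ACA-ATA	2	T-I	1	edited	0
rps2	248	TCA-TTA	2	S-L	1	edited	0
rps3	30	TTC-TTT	3	I-I	0	unedited	0
rps3	470	ACA-ATA	2	S-L	0	partial	1
rps3	583	CAT-TAT	1	S-L	0	edited	1
rps3	627	ATC-ATT	3	I-I	0	unedited	0
rps7	300	GCC-GCT	3	A-A	0	unedited	0
rps8	141	AAT-AAC	3	N-N	0	unedited	0
rps8	182	TCA-TTA	2	S-L	1	edited	0
rps14	80	TCA-TTA	2	S-L	1	edited	0
rps14	149	CCA-CTA	2	P-L	1	edited	0
ycf1	3423	TAC-TAT	3	Y-Y	0	unedited	0
ycf1	3429	GAT-GAC	3	D-D	0	unedited	0
ycf1	3449	ATT-ACT	2	I-T	0	unedited	0
ycf1	3852	ATC-ATT	3	I-I	0	unedited	0
ycf1	4487	CTT-CCT	2	L-P	0	unedited	0
ycf2	549	TCG-TCA	3	S-S	0	unedited	0
ycf2	607	GAA-AAA	1	E-K	0	unedited	0
ycf3	44	TCT-TTT	2	S-F	1	edited	0
ycf3	185	ACG-ATG	2	T-M	1	edited	0
ycf3	191	CCA-CTA	2	P-L	1	edited	0
ycf3	407	TCC-TTC	2	S-F	1	edited	0
ycf4	254	TCA-TTA	2	S-L	0	partial	1
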