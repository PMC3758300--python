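no	size	positions	copies	type	sequence	region	note
1	30	64504,64537	2	D	TATACTATAATAAATATACTATAATAAATA	LSC; spacer between psbE and petL
2	24	91629,91653,91677	3	T	GATATCGATATTGATGATAGTGAC	IRB; ycf2 gene
3	24	146981,147005,147029	3	T	ATATCGTCACTATCATCAATATCG	IRA; ycf2 gene
4	21	149421,149442	2	T	GAAGTGACTTGGACAAAAAGA	IRA; ycf2 gene
5	20	31427,31447	2	T	TTAAAAGATATACTCTGGAA	LSC; spacer between trnT and psbD
6	20	82734,82754	2	T	CTCGTTTACAAATATCCAAA	LSC; 3' end of rps3 gene
7	19	64518,64537	2	T	TATACTATAATAAATATAC	LSC; spacer between psbE and petL
8	17	12731,12748	2	T	TTCTTTATTTGTATTTG	LSC; intron of atpF gene
9	13	28852,28873	2	D	TATTATATATAAA	LSC; spacer between petN and psbM
10	13	59048	1	I	TATTATATATAAA	LSC; spacer between petN and psbM, spacer between accD and psaI	inverted_of_9
11	12	3749,3773,3793	3	D	AATTAAATAATA	LSC; intron of trnK
12	12	35106,35118,35141	3	T	ACTACTATACTA	LSC; spacer between trnG and trnfM
13	12	35167	1	I	ACTACTATACTA	LSC; spacer between trnG and trnfM	inverted_of_12
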